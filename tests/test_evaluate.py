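"""Accuracy curves, AUC improvement, family averaging, threshold sweep."""

import numpy as np
import pytest

from codoncma import (
    AccuracyCurve,
    ColumnMapping,
    ContactMap,
    StructureChain,
    auc_improvement,
    evaluate_ranking,
    family_evaluation,
    threshold_sweep,
)
from codoncma.evaluate import _select_structures
from codoncma.scores import ScoreMatrix


def toy_cmap(n, pairs, min_separation=1):
    mat = np.zeros((n, n), dtype=bool)
    for i, j in pairs:
        mat[i, j] = mat[j, i] = True
    return ContactMap(mat, "cbeta", 8.0, min_separation)


class TestEvaluateRanking:
    def test_all_correct(self):
        cmap = toy_cmap(12, [(0, 6), (1, 7), (2, 8)])
        curve = evaluate_ranking([(0, 6), (1, 7), (2, 8)], cmap)
        assert np.all(curve.accuracy == 1.0)

    def test_four_of_ten(self):
        truth = [(0, k) for k in range(5, 9)]
        preds = truth + [(1, k) for k in range(6, 12)]
        cmap = toy_cmap(15, truth)
        # put the 4 correct ones anywhere within the top 10
        preds = [preds[i] for i in [4, 0, 5, 1, 6, 7, 2, 8, 9, 3]]
        curve = evaluate_ranking(preds, cmap, n_range=np.array([10]))
        assert curve.accuracy[0] == pytest.approx(0.4)

    def test_random_ranking_matches_density(self):
        rng = np.random.default_rng(77)
        n = 40
        pairs = [(i, j) for i in range(n) for j in range(i + 5, n)]
        truth = [pairs[k] for k in rng.choice(len(pairs), size=len(pairs) // 4,
                                              replace=False)]
        cmap = toy_cmap(n, truth, min_separation=5)
        order = rng.permutation(len(pairs))
        curve = evaluate_ranking([pairs[k] for k in order], cmap)
        density = len(truth) / len(pairs)
        # accuracy over all predictions equals the density exactly,
        # and at half the list it should be within binomial error
        assert curve.accuracy[-1] == pytest.approx(density)
        half = len(pairs) // 2
        se = np.sqrt(density * (1 - density) / half)
        assert abs(curve.accuracy[half - 1] - density) < 4 * se

    def test_truncation_warns(self):
        cmap = toy_cmap(12, [(0, 6)])
        with pytest.warns(UserWarning, match="truncated"):
            curve = evaluate_ranking(
                [(0, 6), (1, 7)], cmap, n_range=np.arange(1, 10)
            )
        assert curve.n_values.max() == 2

    def test_unmapped_columns_skipped(self):
        cmap = toy_cmap(10, [(0, 5)])
        mapping = ColumnMapping({0: 0, 5: 5}, 0.2)
        curve = evaluate_ranking([(0, 9), (0, 5)], cmap, mapping)
        # (0, 9) cannot be verified; only (0, 5) survives and is correct
        assert len(curve.accuracy) == 1
        assert curve.accuracy[0] == 1.0


class TestAucImprovement:
    def test_identical_curves_zero(self):
        grid = np.arange(1, 6)
        c = AccuracyCurve(grid, np.linspace(1, 0.5, 5))
        assert auc_improvement(c, c) == 0.0

    def test_doubled_curve_hundred_percent(self):
        grid = np.arange(1, 6)
        base = AccuracyCurve(grid, np.full(5, 0.3))
        combined = AccuracyCurve(grid, np.full(5, 0.6))
        assert auc_improvement(base, combined) == pytest.approx(100.0)

    def test_hand_trapezoid(self):
        grid = np.array([1, 2, 3, 4, 5])
        a = np.array([1.0, 0.8, 0.6, 0.5, 0.4])
        b = np.array([1.0, 0.9, 0.8, 0.6, 0.5])
        auc_a = sum((a[k] + a[k + 1]) / 2 for k in range(4))
        auc_b = sum((b[k] + b[k + 1]) / 2 for k in range(4))
        expected = 100 * (auc_b - auc_a) / auc_a
        got = auc_improvement(AccuracyCurve(grid, a), AccuracyCurve(grid, b))
        assert got == pytest.approx(expected)

    def test_swap_relation(self):
        grid = np.arange(1, 8)
        rng = np.random.default_rng(2)
        a = AccuracyCurve(grid, rng.uniform(0.2, 1, 7))
        b = AccuracyCurve(grid, rng.uniform(0.2, 1, 7))
        fwd = auc_improvement(a, b)
        back = auc_improvement(b, a)
        # improvement(a,b) = 100*D/A and improvement(b,a) = -100*D/B
        assert fwd * a.auc() == pytest.approx(-back * b.auc())

    def test_zero_baseline_errors(self):
        grid = np.arange(1, 4)
        zero = AccuracyCurve(grid, np.zeros(3))
        other = AccuracyCurve(grid, np.ones(3))
        with pytest.raises(ValueError):
            auc_improvement(zero, other)


def _chain_from_coords(cid, coords, sequence, resolution=2.0):
    coords = np.asarray(coords, dtype=float)
    return StructureChain(
        id=cid,
        sequence=sequence,
        cb_coords=coords,
        heavy_coords=[coords[i : i + 1] for i in range(len(coords))],
        resolution=resolution,
    )


class TestFamilyEvaluation:
    def _family(self, n=12):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACDEFHIKLMNPQRSTVWY"), size=n))
        coords = np.column_stack([np.arange(n) * 10.0, np.zeros(n), np.zeros(n)])
        coords[7] = coords[0] + [5.0, 0, 0]  # single contact (0, 7)
        scores = np.zeros((n, n))
        scores[0, 7] = scores[7, 0] = 1.0
        sm = ScoreMatrix(scores, "DCA", "aa", min_separation=5)
        return seq, coords, sm

    def test_two_structure_average(self):
        seq, coords, sm = self._family()
        good = _chain_from_coords("a", coords, seq)
        # second structure (one mutation: still >80% identical) without
        # the contact: accuracy 0 everywhere
        far = coords.copy()
        far[7] = [70.0, 0, 0]
        seq_b = ("W" if seq[0] != "W" else "Y") + seq[1:]
        bad = _chain_from_coords("b", far, seq_b)
        res = family_evaluation({"base": sm}, [good, bad], seq)
        assert res.n_structures == 2
        assert res.curves["base"].accuracy[0] == pytest.approx(0.5)

    def test_caps_at_30_structures(self):
        seq, coords, sm = self._family()
        rng = np.random.default_rng(3)
        letters = "ACDEFHIKLMNPQRSTVWY"
        chains = []
        for k in range(40):
            jitter = coords + rng.normal(0, 0.01, coords.shape)
            # unique sequences: vary the last residue (coverage stays >80%)
            seq_k = seq[:-2] + letters[k % 19] + letters[(k // 19) % 19]
            chains.append(
                _chain_from_coords(f"c{k:02d}", jitter, seq_k, resolution=1.0 + 0.01 * k)
            )
        res = family_evaluation({"base": sm}, chains, seq)
        assert res.n_structures == 30
        # best-resolution selection keeps the 30 smallest
        kept = _select_structures(chains)
        assert all(c.resolution <= 1.0 + 0.01 * 29 + 1e-9 for c in kept)

    def test_single_structure_equals_itself(self):
        seq, coords, sm = self._family()
        chain = _chain_from_coords("a", coords, seq)
        res1 = family_evaluation({"base": sm}, [chain], seq)
        assert res1.n_structures == 1
        assert res1.curves["base"].accuracy[0] == 1.0

    def test_order_invariance(self):
        seq, coords, sm = self._family()
        a = _chain_from_coords("a", coords, seq, resolution=1.5)
        far = coords.copy()
        far[7] = [70.0, 0, 0]
        seq_b = ("W" if seq[0] != "W" else "Y") + seq[1:]
        b = _chain_from_coords("b", far, seq_b, resolution=2.5)
        r1 = family_evaluation({"base": sm}, [a, b], seq)
        r2 = family_evaluation({"base": sm}, [b, a], seq)
        assert np.allclose(r1.curves["base"].accuracy, r2.curves["base"].accuracy)

    def test_no_coverage_errors(self):
        seq, coords, sm = self._family()
        chain = _chain_from_coords("a", coords, "W" * len(seq))
        with pytest.raises(ValueError, match="coverage"):
            family_evaluation({"base": sm}, [chain], seq)

    def test_improvement_reported(self):
        seq, coords, sm = self._family()
        chain = _chain_from_coords("a", coords, seq)
        worse = ScoreMatrix(np.zeros_like(sm.scores), "DCA", "aa", 5)
        res = family_evaluation({"base": sm, "combined": sm}, [chain], seq)
        assert res.improvement_percent == pytest.approx(0.0)
        assert "combined" in res.auc


class TestThresholdSweep:
    def test_duplicate_thresholds_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([], [6.0, 6.0, 8.0])

    def test_single_threshold_matches_family_eval(self):
        rng = np.random.default_rng(8)
        n = 12
        seq = "".join(rng.choice(list("ACDEFHIKLMNPQRSTVWY"), size=n))
        coords = np.column_stack([np.arange(n) * 10.0, np.zeros(n), np.zeros(n)])
        coords[7] = coords[0] + [5.0, 0, 0]
        chain = _chain_from_coords("a", coords, seq)
        scores = np.zeros((n, n))
        scores[0, 7] = scores[7, 0] = 1.0
        sm = ScoreMatrix(scores, "DCA", "aa", min_separation=5)
        fam = {"score_matrices": {"base": sm, "combined": sm},
               "structures": [chain], "domain_seq": seq}
        sweep = threshold_sweep([fam], [8.0])
        direct = family_evaluation({"base": sm, "combined": sm}, [chain], seq,
                                   threshold=8.0)
        assert sweep[0] == pytest.approx(direct.improvement_percent)
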