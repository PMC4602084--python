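"""Alphabets, alignment I/O, codon threading, reweighting, frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codoncma import (
    AA_ALPHABET,
    CODON_ALPHABET,
    STANDARD_CODE,
    Msa,
    build_codon_msa,
    compute_weights,
    read_msa,
    site_frequencies,
    translate_msa,
    write_msa,
)

from conftest import make_aa_msa


class TestAlphabets:
    def test_state_counts(self):
        assert AA_ALPHABET.size == 21
        assert CODON_ALPHABET.size == 65

    def test_gap_is_member_and_unknown_maps_to_gap(self):
        assert AA_ALPHABET.index("-") == AA_ALPHABET.gap_state
        assert AA_ALPHABET.index("X") == AA_ALPHABET.gap_state
        assert CODON_ALPHABET.index("NNN") == CODON_ALPHABET.gap_state

    def test_genetic_code_total(self):
        assert len(STANDARD_CODE.table) == 64
        assert STANDARD_CODE.translate("ATGAAATAA") == "MK*"


class TestReadWrite:
    def test_fasta_protein_roundtrip(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">r1\nMKLV\n>r2\nM-LX\n")
        msa = read_msa(path, "fasta", AA_ALPHABET)
        assert (msa.n_sequences, msa.n_columns) == (2, 4)
        assert msa.ids == ["r1", "r2"]
        # X becomes the gap state
        assert msa.states[1, 3] == AA_ALPHABET.gap_state
        out = tmp_path / "b.fasta"
        write_msa(msa, out, "fasta")
        again = read_msa(out, "fasta", AA_ALPHABET)
        assert np.array_equal(again.states, msa.states)
        assert again.ids == msa.ids

    def test_stockholm_roundtrip(self, tmp_path):
        msa = make_aa_msa(["MKLV", "MRLV", "M-LV"])
        path = tmp_path / "a.sto"
        write_msa(msa, path, "stockholm")
        again = read_msa(path, "stockholm", AA_ALPHABET)
        assert np.array_equal(again.states, msa.states)
        assert again.ids == msa.ids

    def test_codon_tokenization(self, tmp_path):
        path = tmp_path / "c.fasta"
        path.write_text(">r1\nATG---AAA\n")
        msa = read_msa(path, "fasta", CODON_ALPHABET)
        assert msa.n_columns == 3
        toks = [CODON_ALPHABET.symbols[s] for s in msa.states[0]]
        assert toks == ["ATG", "---", "AAA"]

    def test_ambiguous_codon_becomes_gap(self, tmp_path):
        path = tmp_path / "c.fasta"
        path.write_text(">r1\nATGANAAAA\n")
        msa = read_msa(path, "fasta", CODON_ALPHABET)
        assert msa.states[0, 1] == CODON_ALPHABET.gap_state

    def test_ragged_alignment_names_offender(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">ok\nMKLV\n>short\nMK\n")
        with pytest.raises(ValueError, match="short"):
            read_msa(path, "fasta", AA_ALPHABET)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError):
            read_msa(path, "fasta", AA_ALPHABET)


class TestCodonThreading:
    def test_gap_threading(self):
        protein = make_aa_msa(["M-K"], ids=["a"])
        codon = build_codon_msa(protein, {"a": "ATGAAA"})
        toks = [CODON_ALPHABET.symbols[s] for s in codon.states[0]]
        assert toks == ["ATG", "---", "AAA"]

    def test_trailing_stop_stripped(self):
        protein = make_aa_msa(["MK"], ids=["a"])
        codon = build_codon_msa(protein, {"a": "ATGAAATAA"})
        assert codon.n_columns == 2

    def test_translation_mismatch_position_reported(self):
        protein = make_aa_msa(["MK"], ids=["a"])
        with pytest.raises(ValueError, match="position 2"):
            build_codon_msa(protein, {"a": "ATGGGG"})

    def test_missing_cds_lists_ids(self):
        protein = make_aa_msa(["MK", "MR"], ids=["a", "b"])
        with pytest.raises(KeyError, match="b"):
            build_codon_msa(protein, {"a": "ATGAAA"})

    def test_length_not_divisible_by_three(self):
        protein = make_aa_msa(["MK"], ids=["a"])
        with pytest.raises(ValueError, match="divisible"):
            build_codon_msa(protein, {"a": "ATGAA"})

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_translation_property(self, seed):
        """Threading then translating reproduces the protein alignment."""
        rng = np.random.default_rng(seed)
        m, length = 10, 20
        sense_codons = [
            c for c in CODON_ALPHABET.symbols[:-1] if not STANDARD_CODE.is_stop(c)
        ]
        rows, cds = [], {}
        for s in range(m):
            codons = [sense_codons[k] for k in rng.integers(0, len(sense_codons), length)]
            gaps = rng.random(length) < 0.2
            row = "".join(
                "-" if g else STANDARD_CODE.translate_codon(c)
                for c, g in zip(codons, gaps)
            )
            rows.append(row)
            cds[f"s{s}"] = "".join(c for c, g in zip(codons, gaps) if not g)
        protein = make_aa_msa(rows)
        codon = build_codon_msa(protein, cds)
        back = translate_msa(codon)
        assert np.array_equal(back.states, protein.states)


class TestWeights:
    def test_identical_sequences(self):
        msa = make_aa_msa(["MKLV"] * 5)
        w, meff = compute_weights(msa)
        assert np.allclose(w, 0.2)
        assert meff == pytest.approx(1.0)

    def test_all_distinct(self):
        msa = make_aa_msa(["MKLV", "ACDE", "FHIW", "PQRS"])
        w, meff = compute_weights(msa, 0.8)
        assert np.allclose(w, 1.0)
        assert meff == pytest.approx(4.0)

    def test_two_clusters_brute_force(self):
        # cluster of 4 (>=80% pairwise identity) and cluster of 2
        rows = ["MKLVAAAAAA", "MKLVAAAAAC", "MKLVAAAACA", "MKLVAAACAA",
                "WWWWWWWWWW", "WWWWWWWWWC"]
        msa = make_aa_msa(rows)
        # independent brute-force identity matrix
        ident = np.array(
            [[np.mean([a == b for a, b in zip(r1, r2)]) for r2 in rows] for r1 in rows]
        )
        expected = 1.0 / (ident >= 0.8).sum(axis=1)
        w, meff = compute_weights(msa, 0.8)
        assert np.allclose(w, expected)
        assert np.allclose(w, [0.25] * 4 + [0.5] * 2)
        assert meff == pytest.approx(2.0)

    def test_permutation_equivariance(self, random_aa_msa):
        w, _ = compute_weights(random_aa_msa)
        perm = np.random.default_rng(0).permutation(random_aa_msa.n_sequences)
        permuted = Msa(
            random_aa_msa.states[perm],
            [random_aa_msa.ids[p] for p in perm],
            AA_ALPHABET,
        )
        wp, _ = compute_weights(permuted)
        assert np.allclose(wp, w[perm])


class TestFrequencies:
    def test_single_sequence_indicator(self):
        msa = make_aa_msa(["MK"])
        f = site_frequencies(msa, lam=0.0)
        assert f.f_single[0, AA_ALPHABET.index("M")] == 1.0
        assert f.f_single.sum() == pytest.approx(2.0)

    def test_large_pseudocount_flattens(self):
        msa = make_aa_msa(["MK", "MR"])
        f = site_frequencies(msa, lam=1e9)
        assert np.allclose(f.f_single, 1 / 21, atol=1e-6)
        assert np.allclose(f.f_pair, 1 / 21**2, atol=1e-6)

    def test_matches_naive_counter(self):
        rng = np.random.default_rng(7)
        states = rng.integers(0, 21, size=(5, 3))
        msa = Msa(states, list("abcde"), AA_ALPHABET)
        lam = 0.5
        f = site_frequencies(msa, lam=lam)
        q, m = 21, 5
        for i in range(3):
            for a in range(q):
                naive = (lam / q + (states[:, i] == a).sum()) / (lam + m)
                assert f.f_single[i, a] == pytest.approx(naive)
        for i in range(3):
            for j in range(3):
                for a in range(q):
                    for b in range(0, q, 5):
                        naive = (
                            lam / q**2
                            + ((states[:, i] == a) & (states[:, j] == b)).sum()
                        ) / (lam + m)
                        assert f.f_pair[i, j, a, b] == pytest.approx(naive)

    def test_normalization_and_marginalization(self, random_aa_msa):
        f = site_frequencies(random_aa_msa, lam=0.0)
        assert np.allclose(f.f_single.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(f.f_pair.sum(axis=(2, 3)), 1.0, atol=1e-9)
        marg = f.f_pair.sum(axis=3)
        for j in range(f.n_columns):
            assert np.allclose(marg[:, j, :], f.f_single, atol=1e-9)
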