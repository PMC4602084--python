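"""Accuracy curves, AUC improvement, and per-family evaluation.

Accuracy at N is the proportion of true contacts among the N
highest-scoring valid pairs.  The improvement brought by codon
information is the percent change in the trapezoidal area under the
accuracy-vs-N curve relative to the amino-acid-only baseline, averaged
over (up to 30) structures per family so that well-crystallised families
are not over-represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .scores import ScoreMatrix, rank_pairs
from .structure import ColumnMapping, ContactMap, StructureChain, contact_map, map_columns_to_structure

__all__ = [
    "AccuracyCurve",
    "FamilyEvalResult",
    "evaluate_ranking",
    "auc_improvement",
    "family_evaluation",
    "threshold_sweep",
]

MAX_STRUCTURES_PER_FAMILY = 30


@dataclass
class AccuracyCurve:
    """Accuracy (fraction of true contacts) as a function of top-N."""

    n_values: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self) -> None:
        self.n_values = np.asarray(self.n_values, dtype=int)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.n_values.shape != self.accuracy.shape:
            raise ValueError("n_values and accuracy must align")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    def fraction_of_length(self, length: int) -> np.ndarray:
        """The same x-axis expressed as a fraction of chain length."""
        return self.n_values / length

    def auc(self) -> float:
        return float(np.trapezoid(self.accuracy, self.n_values))


@dataclass
class FamilyEvalResult:
    """Per-family averaged accuracy curves and the AUC improvement."""

    curves: dict[str, AccuracyCurve]
    auc: dict[str, float]
    improvement_percent: float | None
    n_structures: int


def evaluate_ranking(
    ranked: list[tuple[int, int]],
    cmap: ContactMap,
    mapping: ColumnMapping | None = None,
    n_range: np.ndarray | None = None,
) -> AccuracyCurve:
    """Accuracy curve of a ranked pair list against a contact map.

    Predictions whose columns are not covered by ``mapping`` are skipped
    (they cannot be verified).  If ``n_range`` extends past the number of
    mappable predictions, the curve is truncated with a warning.
    """
    if mapping is None:
        mapping = ColumnMapping.identity(cmap.n_residues)
    hits = []
    for i, j in ranked:
        ri = mapping.col_to_res.get(i)
        rj = mapping.col_to_res.get(j)
        if ri is None or rj is None:
            continue
        hits.append(bool(cmap.contacts[ri, rj]))
    hits_arr = np.array(hits, dtype=float)
    if n_range is None:
        n_range = np.arange(1, len(hits_arr) + 1)
    n_range = np.asarray(n_range, dtype=int)
    if len(n_range) == 0 or len(hits_arr) == 0:
        raise ValueError("no evaluable predictions")
    if n_range.max() > len(hits_arr):
        warnings.warn(
            f"requested top-{n_range.max()} but only {len(hits_arr)} "
            "mappable predictions; curve truncated"
        )
        n_range = n_range[n_range <= len(hits_arr)]
    cum = np.cumsum(hits_arr)
    return AccuracyCurve(n_range, cum[n_range - 1] / n_range)


def auc_improvement(curve_base: AccuracyCurve, curve_combined: AccuracyCurve) -> float:
    """Percent AUC change of the combined curve over the baseline.

    100 * (AUC_combined - AUC_base) / AUC_base, trapezoidal AUCs on a
    shared N grid.
    """
    if not np.array_equal(curve_base.n_values, curve_combined.n_values):
        raise ValueError("curves must share the same N grid")
    auc_base = curve_base.auc()
    if auc_base == 0:
        raise ValueError("baseline AUC is zero; improvement undefined")
    return float(100.0 * (curve_combined.auc() - auc_base) / auc_base)


def _select_structures(
    structures: list[StructureChain],
) -> list[StructureChain]:
    """Up to 30 unique-sequence structures, best resolution first.

    Resolution ties are broken by lexicographically smallest identifier;
    duplicate sequences keep only their best representative.
    """
    def key(c: StructureChain):
        res = c.resolution if c.resolution is not None else np.inf
        return (res, c.id)

    seen: dict[str, StructureChain] = {}
    for chain in sorted(structures, key=key):
        if chain.sequence not in seen:
            seen[chain.sequence] = chain
    return list(seen.values())[:MAX_STRUCTURES_PER_FAMILY]


def family_evaluation(
    score_matrices: dict[str, ScoreMatrix],
    structures: list[StructureChain],
    domain_seq: str,
    definition: str = "cbeta",
    threshold: float = 8.0,
    min_separation: int = 5,
    n_range: np.ndarray | None = None,
    baseline: str = "base",
    combined: str = "combined",
) -> FamilyEvalResult:
    """Average the per-structure accuracy curves of each score variant.

    Structures failing the 80% coverage rule are dropped; if none pass,
    an error is raised.  The AUC improvement is reported whenever both
    the ``baseline`` and ``combined`` variants are present.
    """
    chosen = _select_structures(structures)
    usable: list[tuple[StructureChain, ColumnMapping]] = []
    for chain in chosen:
        mapping = map_columns_to_structure(domain_seq, chain)
        if mapping.passes_inclusion:
            usable.append((chain, mapping))
    if not usable:
        raise ValueError("no structure passes the 80% coverage rule")

    if n_range is None:
        n_range = np.arange(1, len(domain_seq) + 1)

    curves: dict[str, AccuracyCurve] = {}
    for name, sm in score_matrices.items():
        ranked = rank_pairs(sm)
        per_structure = []
        grid = None
        for chain, mapping in usable:
            cmap = contact_map(chain, definition, threshold, min_separation)
            curve = evaluate_ranking(ranked, cmap, mapping, n_range)
            per_structure.append(curve.accuracy)
            grid = curve.n_values if grid is None else grid
            if len(curve.n_values) != len(grid):
                raise ValueError("structures yield inconsistent curve lengths")
        curves[name] = AccuracyCurve(grid, np.mean(per_structure, axis=0))

    aucs = {name: c.auc() for name, c in curves.items()}
    improvement = None
    if baseline in curves and combined in curves:
        improvement = auc_improvement(curves[baseline], curves[combined])
    return FamilyEvalResult(curves, aucs, improvement, n_structures=len(usable))


def threshold_sweep(
    families: list[dict],
    thresholds: list[float],
    definition: str = "cbeta",
    **kwargs,
) -> "np.ndarray":
    """Mean percent AUC improvement across families per contact threshold.

    ``families`` holds keyword dictionaries for :func:`family_evaluation`
    (score_matrices, structures, domain_seq).  Returns an array aligned
    with ``thresholds``.
    """
    arr = np.asarray(thresholds, dtype=float)
    if len(arr) == 0 or np.any(arr <= 0):
        raise ValueError("thresholds must be positive")
    if np.any(np.diff(arr) <= 0):
        raise ValueError("thresholds must be strictly ascending (no duplicates)")
    means = []
    for t in arr:
        imps = [
            family_evaluation(definition=definition, threshold=float(t), **fam, **kwargs).improvement_percent
            for fam in families
        ]
        means.append(float(np.mean([i for i in imps if i is not None])))
    return np.array(means)
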