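"""Pair scores on alignment columns: OMES, MI, APC-corrected MI, ranking.

Every scorer returns a :class:`ScoreMatrix` — a symmetric L x L matrix
tagged with the method and alphabet it came from.  Pairs closer in
sequence than ``min_separation`` (and the diagonal) are excluded from
ranking, matching the convention that trivially close residues carry no
contact information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .frequencies import FrequencyModel

__all__ = ["ScoreMatrix", "omes_scores", "mi_scores", "apc_correct", "rank_pairs"]

DEFAULT_MIN_SEPARATION = 5


@dataclass
class ScoreMatrix:
    """Symmetric matrix of pair scores with provenance tags."""

    scores: np.ndarray
    method: str
    alphabet_tag: str
    min_separation: int = DEFAULT_MIN_SEPARATION

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise ValueError("scores must be a square matrix")
        if not np.allclose(self.scores, self.scores.T, atol=1e-8, equal_nan=True):
            raise ValueError("scores must be symmetric")

    @property
    def n_columns(self) -> int:
        return self.scores.shape[0]

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of scorable pairs: |i - j| >= min_separation."""
        idx = np.arange(self.n_columns)
        return np.abs(idx[:, None] - idx[None, :]) >= self.min_separation

    def to_table(self):
        """Ranked pairs as a DataFrame with 1-based positions."""
        import pandas as pd

        pairs = rank_pairs(self)
        return pd.DataFrame(
            {
                "i": [i + 1 for i, _ in pairs],
                "j": [j + 1 for _, j in pairs],
                "score": [self.scores[i, j] for i, j in pairs],
                "method": self.method,
                "alphabet": self.alphabet_tag,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def omes_scores(
    freq: FrequencyModel,
    alphabet_tag: str = "aa",
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ScoreMatrix:
    """Observed-minus-expected-squared statistic.

    S(i,j) = sum_ab (OBS_ab - EXP_ab)^2 over the pair count table of
    columns i and j, with EXP_ab = M f(i,a) f(j,b) the product-model
    expectation.  Requires raw counting frequencies (no pseudocount).
    """
    if freq.lam != 0:
        raise ValueError("OMES is defined on raw counts; use lam=0 frequencies")
    m = freq.total_weight
    obs = m * freq.f_pair
    exp = m * np.einsum("ia,jb->ijab", freq.f_single, freq.f_single)
    s = ((obs - exp) ** 2).sum(axis=(2, 3))
    np.fill_diagonal(s, 0.0)
    s = 0.5 * (s + s.T)
    return ScoreMatrix(s, "OMES", alphabet_tag, min_separation)


def mi_scores(
    freq: FrequencyModel,
    alphabet_tag: str = "aa",
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ScoreMatrix:
    """Mutual information between columns, in nats.

    S(i,j) = sum_ab f(i,a;j,b) log [ f(i,a;j,b) / (f(i,a) f(j,b)) ],
    with the usual convention 0 log 0 = 0.
    """
    fij = freq.f_pair
    prod = np.einsum("ia,jb->ijab", freq.f_single, freq.f_single)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(fij > 0, fij * (np.log(fij) - np.log(prod)), 0.0)
    s = terms.sum(axis=(2, 3))
    np.fill_diagonal(s, 0.0)
    s = np.maximum(0.5 * (s + s.T), 0.0)
    return ScoreMatrix(s, "MI", alphabet_tag, min_separation)


def apc_correct(mi: ScoreMatrix) -> ScoreMatrix:
    """Subtract the average product correction from an MI-type matrix.

    APC(i,j) = MI(i,.) MI(j,.) / MI_bar, where MI(i,.) is the mean score
    of column i against all other columns and MI_bar the mean over all
    off-diagonal pairs; the corrected score may be negative.  A constant
    matrix is corrected to exactly zero.
    """
    s = mi.scores.copy()
    length = s.shape[0]
    if length < 2:
        raise ValueError("APC needs at least two columns")
    np.fill_diagonal(s, 0.0)
    col_mean = s.sum(axis=1) / (length - 1)
    grand = s.sum() / (length * (length - 1))
    if grand == 0:
        warnings.warn("mean MI is zero; APC-corrected scores set to zero")
        corrected = np.zeros_like(s)
    else:
        corrected = s - np.outer(col_mean, col_mean) / grand
        np.fill_diagonal(corrected, 0.0)
    method = mi.method + "p" if mi.method == "MI" else mi.method + "+APC"
    return replace(mi, scores=corrected, method=method)


def rank_pairs(score: ScoreMatrix) -> list[tuple[int, int]]:
    """Valid pairs sorted by descending score.

    Only pairs with j - i >= min_separation are ranked; ties are broken
    by ascending (i, j), so the ordering is fully deterministic.
    Positions are 0-based.
    """
    mask = np.triu(score.valid_mask())
    ii, jj = np.nonzero(mask)
    vals = score.scores[ii, jj]
    order = np.lexsort((jj, ii, -vals))
    return [(int(ii[k]), int(jj[k])) for k in order]
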