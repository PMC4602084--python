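"""Nonparametric significance tests on per-family improvements.

Two complementary tests: the sign test (counts of improved vs worsened
families only) and the Wilcoxon signed-rank test (counts and
magnitudes).  Both are two-sided by default; zero deltas are dropped
before testing, following the standard signed-rank convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ImprovementSummary",
    "sign_test",
    "wilcoxon_signed_rank",
    "summarize_improvements",
]


@dataclass
class ImprovementSummary:
    """Counts, median effect, and both p-values for a family set."""

    n_improved: int
    n_worsened: int
    n_tied: int
    median_improvement: float
    p_wilcoxon: float
    p_sign: float

    def __str__(self) -> str:
        return (
            f"{self.n_improved} improved / {self.n_worsened} worsened "
            f"/ {self.n_tied} tied; median {self.median_improvement:+.3f}%; "
            f"Wilcoxon p = {self.p_wilcoxon:.3g}, sign p = {self.p_sign:.3g}"
        )


def _clean(deltas) -> np.ndarray:
    arr = np.asarray(deltas, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("deltas must be a nonempty 1-D sequence")
    nz = arr[arr != 0]
    if nz.size == 0:
        raise ValueError("all deltas are zero; test undefined")
    return nz


def sign_test(deltas, alternative: str = "two-sided") -> float:
    """Exact binomial sign test on the signs of the deltas.

    Ties (zeros) are dropped; under the null, positives are Binomial(n,
    1/2).  Ten positives out of ten give p = 2 * 0.5^10 = 0.001953125.
    """
    nz = _clean(deltas)
    k = int((nz > 0).sum())
    return float(sps.binomtest(k, nz.size, 0.5, alternative=alternative).pvalue)


def wilcoxon_signed_rank(
    deltas, mode: str = "auto", alternative: str = "two-sided"
) -> float:
    """Two-sided (by default) Wilcoxon signed-rank p-value.

    ``mode``: "exact" enumerates the null distribution (n <= 25 and no
    tied magnitudes), "asymptotic" uses the normal approximation with
    tie and continuity corrections, "auto" picks exact when possible.
    """
    nz = _clean(deltas)
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode: {mode!r}")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    if mode == "exact":
        if nz.size > 25:
            raise ValueError("exact mode limited to n <= 25")
        if has_ties:
            raise ValueError("exact mode undefined with tied magnitudes")
        method = "exact"
    elif mode == "asymptotic":
        method = "approx"
    else:
        method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, alternative=alternative, method=method, correction=True)
    return float(res.pvalue)


def summarize_improvements(deltas, mode: str = "auto") -> ImprovementSummary:
    """Assemble counts, median, and both p-values for per-family deltas."""
    arr = np.asarray(deltas, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two families to summarise")
    return ImprovementSummary(
        n_improved=int((arr > 0).sum()),
        n_worsened=int((arr < 0).sum()),
        n_tied=int((arr == 0).sum()),
        median_improvement=float(np.median(arr)),
        p_wilcoxon=wilcoxon_signed_rank(arr, mode=mode),
        p_sign=sign_test(arr),
    )
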