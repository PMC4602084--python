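"""Sparse inverse-covariance contact scoring (PSICOV-style).

Columns are one-hot encoded over q-1 states (gap dropped), the weighted
sample covariance is shrunk toward its diagonal until positive definite,
and a sparse precision matrix is estimated by L1-penalised maximum
likelihood (graphical lasso).  The pair score is the L1 norm of the
corresponding precision block, optionally followed by the average
product correction; the variant without APC is labelled ``PSICOV*``.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.covariance import graphical_lasso

from .msa import Msa, compute_weights
from .scores import DEFAULT_MIN_SEPARATION, ScoreMatrix, apc_correct
from .dca import MEMORY_GUARD_DIM

__all__ = ["psicov_scores", "DIVERSITY_THRESHOLD"]

#: minimum effective sequence number accepted when the diversity check is on
DIVERSITY_THRESHOLD = 125.0


class DiversityError(ValueError):
    """Alignment too shallow for sparse inverse-covariance estimation."""


def psicov_scores(
    msa: Msa,
    rho: float = 0.001,
    apply_apc: bool = True,
    diversity_check: bool = True,
    identity_threshold: float = 0.8,
    alphabet_tag: str | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    max_iter: int = 200,
    memory_guard: bool = True,
) -> ScoreMatrix:
    """Precision-matrix pair scores with L1 penalty ``rho``.

    S(i,j) = sum_ab |Theta(i,a; j,b)| over the q-1 non-gap states.  With
    ``apply_apc`` off the result is the PSICOV* variant.  Raises
    :class:`DiversityError` when the effective sequence number falls
    below :data:`DIVERSITY_THRESHOLD` and the check is enabled, and
    ``FloatingPointError`` on non-convergence.
    """
    q = msa.alphabet.size
    length = msa.n_columns
    qr = q - 1
    dim = length * qr
    if memory_guard and dim > MEMORY_GUARD_DIM:
        raise MemoryError(
            f"encoded dimension L*(q-1) = {dim} exceeds the guard "
            f"({MEMORY_GUARD_DIM}); pass memory_guard=False to override"
        )

    weights, meff = compute_weights(msa, identity_threshold)
    if diversity_check and meff < DIVERSITY_THRESHOLD:
        raise DiversityError(
            f"effective sequence number {meff:.1f} is below this method's "
            f"threshold for sequence diversity ({DIVERSITY_THRESHOLD:.0f}); "
            "pass diversity_check=False to override"
        )

    m = msa.n_sequences
    onehot = np.zeros((m, dim))
    keep = msa.states < qr  # gap state (last) is dropped from the encoding
    rows, cols = np.nonzero(keep)
    onehot[rows, cols * qr + msa.states[rows, cols]] = 1.0

    wnorm = weights / weights.sum()
    mean = wnorm @ onehot
    centered = onehot - mean
    cov = (centered * wnorm[:, None]).T @ centered

    # shrink toward the mean-variance identity until comfortably positive
    # definite; a uniform diagonal target also lifts the zero-variance
    # coordinates of never-observed states, which the sample covariance
    # leaves exactly singular
    mean_var = float(np.mean(np.diag(cov)))
    target = mean_var * np.eye(dim)
    gamma = 0.0
    shrunk = cov
    while np.linalg.eigvalsh(shrunk)[0] <= 1e-6 * mean_var and gamma < 1.0:
        gamma = min(gamma + 0.05, 1.0)
        shrunk = (1 - gamma) * cov + gamma * target

    # highly collinear alignments (near-duplicate columns) can still defeat
    # the solver; shrink harder until it converges, as the reference
    # implementation does
    precision = None
    last_err: Exception | None = None
    while gamma <= 0.95:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, precision = graphical_lasso(shrunk, alpha=rho, max_iter=max_iter)
            break
        except FloatingPointError as err:
            last_err = err
            gamma += 0.1
            shrunk = (1 - gamma) * cov + gamma * target
    if precision is None:
        raise FloatingPointError(
            f"graphical lasso did not converge at rho={rho} even under "
            f"maximal shrinkage: {last_err}"
        )

    s = np.zeros((length, length))
    absprec = np.abs(precision)
    for i in range(length):
        for j in range(i + 1, length):
            s[i, j] = s[j, i] = absprec[
                i * qr : (i + 1) * qr, j * qr : (j + 1) * qr
            ].sum()

    tag = alphabet_tag or msa.alphabet.name
    result = ScoreMatrix(s, "PSICOV*", tag, min_separation)
    if apply_apc:
        result = apc_correct(result)
        result.method = "PSICOV"
    return result
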