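"""Mean-field direct coupling analysis (direct information scores).

The classic mean-field recipe: reweight sequences by identity, estimate
pseudocounted single and pair frequencies, build the connected
correlation matrix over q-1 states per column (the gap state is the
gauge state and is dropped), invert it to obtain couplings, and for each
column pair compute the direct information — the mutual information of
the two-site "direct" distribution whose fields are fitted so that its
marginals match the single-site frequencies.
"""

from __future__ import annotations

import numpy as np

from .msa import Msa, compute_weights
from .scores import DEFAULT_MIN_SEPARATION, ScoreMatrix

__all__ = ["mfdca_scores"]

#: refuse correlation matrices larger than this edge length unless overridden
MEMORY_GUARD_DIM = 20_000


def _pseudocounted_frequencies(
    msa: Msa, lam: float, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Single (L,q) and pair (L,L,q,q) frequencies with the DCA pseudocount.

    Off-diagonal pair blocks receive lam/q^2 prior mass; diagonal blocks
    receive lam/q on the diagonal only, so that f(i,i,a,b) stays
    delta_ab f(i,a) after smoothing.
    """
    q = msa.alphabet.size
    m, length = msa.states.shape
    meff = float(weights.sum())

    onehot = np.zeros((m, length, q))
    onehot[np.arange(m)[:, None], np.arange(length)[None, :], msa.states] = 1.0
    single = np.einsum("s,sia->ia", weights, onehot)
    flat = (onehot * weights[:, None, None]).reshape(m, length * q)
    pair = (flat.T @ onehot.reshape(m, length * q)).reshape(length, q, length, q)
    pair = pair.transpose(0, 2, 1, 3)

    fi = (lam / q + single) / (lam + meff)
    fij = (lam / q**2 + pair) / (lam + meff)
    eye = np.eye(q)
    for i in range(length):
        fij[i, i] = (pair[i, i] + lam / q * eye) / (lam + meff)
    return fi, fij


def _fit_direct_distribution(
    w: np.ndarray, fi: np.ndarray, fj: np.ndarray, tol: float, max_iter: int
) -> np.ndarray:
    """Two-site model P(a,b) ∝ W(a,b) mu1(a) mu2(b) with marginals fi, fj.

    Fields are fitted by iterative proportional scaling to ``tol`` in the
    max-norm of the field update.
    """
    q = w.shape[0]
    mu1 = np.full(q, 1.0 / q)
    mu2 = np.full(q, 1.0 / q)
    for _ in range(max_iter):
        scra1 = w @ mu2
        scra2 = w.T @ mu1
        new1 = fi / scra1
        new1 /= new1.sum()
        new2 = fj / scra2
        new2 /= new2.sum()
        diff = max(np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max())
        mu1, mu2 = new1, new2
        if diff < tol:
            break
    pdir = w * np.outer(mu1, mu2)
    return pdir / pdir.sum()


def mfdca_scores(
    msa: Msa,
    lam: float | None = None,
    identity_threshold: float = 0.8,
    alphabet_tag: str | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    fit_tol: float = 1e-4,
    fit_max_iter: int = 500,
    memory_guard: bool = True,
) -> ScoreMatrix:
    """Direct information for every column pair of an alignment.

    ``lam`` is the pseudocount weight on the Meff scale; the default
    (None) uses lam = Meff, the customary 1:1 mix of data and prior for
    mean-field inversion.  Raises if the correlation matrix is singular
    (possible at lam = 0 with degenerate columns).
    """
    q = msa.alphabet.size
    length = msa.n_columns
    dim = length * (q - 1)
    if memory_guard and dim > MEMORY_GUARD_DIM:
        raise MemoryError(
            f"correlation matrix dimension L*(q-1) = {dim} exceeds the "
            f"guard ({MEMORY_GUARD_DIM}); pass memory_guard=False to override"
        )

    weights, meff = compute_weights(msa, identity_threshold)
    if meff <= 1:
        raise ValueError("effective sequence number must exceed 1")
    if lam is None:
        lam = meff

    fi, fij = _pseudocounted_frequencies(msa, lam, weights)

    # connected correlations over the first q-1 states; the dropped state
    # (gap, by construction the last state of both alphabets) is the gauge
    qr = q - 1
    c = (
        fij[:, :, :qr, :qr]
        - np.einsum("ia,jb->ijab", fi[:, :qr], fi[:, :qr])
    )
    cmat = c.transpose(0, 2, 1, 3).reshape(dim, dim)
    try:
        invc = np.linalg.inv(cmat)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; use a positive pseudocount lam"
        ) from err

    di = np.zeros((length, length))
    eps = 1e-12
    for i in range(length):
        for j in range(i + 1, length):
            block = invc[i * qr : (i + 1) * qr, j * qr : (j + 1) * qr]
            w = np.ones((q, q))
            w[:qr, :qr] = np.exp(-block)
            pdir = _fit_direct_distribution(w, fi[i], fi[j], fit_tol, fit_max_iter)
            prod = np.outer(fi[i], fi[j])
            di[i, j] = di[j, i] = float(
                (pdir * np.log((pdir + eps) / (prod + eps))).sum()
            )

    di = np.maximum(di, 0.0)
    tag = alphabet_tag or msa.alphabet.name
    return ScoreMatrix(di, "DCA", tag, min_separation)
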