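"""Weighted, pseudocounted single-site and pair frequency estimates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import Msa

__all__ = ["FrequencyModel", "site_frequencies"]


@dataclass
class FrequencyModel:
    """Empirical frequencies of an alignment.

    ``f_single[i, a]`` estimates the probability of state a at column i,
    ``f_pair[i, j, a, b]`` the joint probability at columns (i, j).  The
    pseudocount weight ``lam`` is expressed on the same scale as Meff:
    each single-site cell receives lam/q prior mass and each pair cell
    lam/q^2, normalised by (lam + Meff).  lam = 0 gives raw (weighted)
    relative counts; lam -> inf flattens everything to 1/q.
    """

    f_single: np.ndarray  # (L, q)
    f_pair: np.ndarray  # (L, L, q, q)
    lam: float
    meff: float
    total_weight: float  # raw sum of sequence weights used for counting

    @property
    def n_columns(self) -> int:
        return self.f_single.shape[0]

    @property
    def n_states(self) -> int:
        return self.f_single.shape[1]

    def entropies(self) -> np.ndarray:
        """Per-column Shannon entropy (nats) from the single-site frequencies."""
        f = self.f_single
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log(f), 0.0)
        return -terms.sum(axis=1)


def site_frequencies(msa: Msa, lam: float = 0.0, use_weights: bool = True) -> FrequencyModel:
    """Single-site and pair frequencies with an optional pseudocount.

    f(i,a) = (lam/q + sum_s w_s 1[x_si = a]) / (lam + Meff), and the pair
    analogue with lam/q^2.  With ``use_weights`` off, all sequences count
    with weight 1 (Meff = M).
    """
    if lam < 0:
        raise ValueError("pseudocount weight must be nonnegative")
    q = msa.alphabet.size
    m, length = msa.states.shape
    w = msa.effective_weights() if use_weights else np.ones(m)
    meff = float(w.sum())

    onehot = np.zeros((m, length, q))
    onehot[np.arange(m)[:, None], np.arange(length)[None, :], msa.states] = 1.0

    single = np.einsum("s,sia->ia", w, onehot)
    flat = (onehot * w[:, None, None]).reshape(m, length * q)
    pair = (flat.T @ onehot.reshape(m, length * q)).reshape(length, q, length, q)
    pair = pair.transpose(0, 2, 1, 3)

    f_single = (lam / q + single) / (lam + meff)
    f_pair = (lam / q**2 + pair) / (lam + meff)
    return FrequencyModel(f_single, f_pair, lam=lam, meff=meff, total_weight=meff)
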