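"""Fit the combination exponent alpha on a set of toy families.

The exponent in S_AA^alpha / S_C controls the relative weight of the
amino-acid and codon channels.  This example fits alpha by maximising
the median percent AUC improvement over synthetic score matrices and
then checks its stability by random half/half cross-validation.
"""

import numpy as np

from codoncma import ContactMap, cv_alpha_stability, fit_alpha
from codoncma.scores import ScoreMatrix


def toy_family(rng, n=12):
    truth = [(0, 5), (1, 8), (3, 10)]
    decoys = [(2, 9), (4, 11)]  # strong at both levels, not contacts
    aa = np.triu(rng.uniform(0.05, 0.15, size=(n, n)), 1)
    codon = np.triu(rng.uniform(0.08, 0.12, size=(n, n)), 1)
    for p in truth:
        aa[p], codon[p] = 0.8 + rng.uniform(0, 0.05), 0.5
    for p in decoys:
        aa[p], codon[p] = 0.9 + rng.uniform(0, 0.05), 3.0
    cmat = np.zeros((n, n), dtype=bool)
    for i, j in truth:
        cmat[i, j] = cmat[j, i] = True
    return (
        ScoreMatrix(aa + aa.T, "DCA", "aa", 2),
        ScoreMatrix(codon + codon.T, "DCA", "codon", 2),
        ContactMap(cmat, "cbeta", 8.0, 2),
    )


rng = np.random.default_rng(3)
families = [toy_family(rng) for _ in range(8)]
grid = np.arange(0.2, 6.01, 0.2)

fit = fit_alpha(families, grid=grid)
print(f"alpha maximising the median AUC improvement: {fit.alpha_max:.1f}")
print(f"median improvement at that alpha: "
      f"{np.median(fit.improvements_at_max):.1f}%")

cv = cv_alpha_stability(families, n_splits=200, seed=7, grid=grid)
print(f"cross-validation over 200 half/half splits: "
      f"mean test improvement {cv['mean_test']:.1f}% "
      f"(learning {cv['mean_learning']:.1f}%)")
print(
    "\nSimilar learning and test means indicate the fitted exponent "
    "generalises rather than overfitting the family set."
)
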