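# Methods

## The statistic

For each pair of alignment columns (i, j) a base method produces a
coevolution score on the amino-acid alignment, S_AA(i, j), and on the
codon alignment of the same sequences, S_C(i, j).  The combined score is

    S(i, j) = max(S_AA, ε)^α / max(S_C, ε),        ε = 1e-10, α > 0.

The rationale: a correlation caused by selection on a protein contact
acts on amino-acid identity, so at the codon level it spreads
indifferently over synonymous codons and the codon score carries little
signal beyond the translated one.  A correlation caused by
nucleic-acid-level constraints or shared ancestry shows up down to the
choice of synonymous codon, inflating S_C.  Dividing by S_C therefore
demotes exactly the pairs most likely to be false positives.  The floor
ε keeps zero and negative scores (possible after the average product
correction) finite and order-preserving among positive scores; since
both MIp and APC-corrected PSICOV can go negative, clamped entries rank
at the bottom, which matches their interpretation as "no signal".

α is fitted by a grid search (default 0.1–20.0, step 0.1) maximising the
median over families of the percent AUC improvement; the per-method
defaults shipped (DCA 2.5, MI 2.5, OMES 1.7, PSICOV* 11.2) are the
optima reported for large Pfam-scale benchmarks.  Random half/half
cross-validation (`cv_alpha_stability`) refits α on a learning half and
scores the held-out half; agreement of learning and test means is the
check that the exponent is not overfitted to the family set.

## Base scorers

All scorers are alphabet-generic and run on q = 21 (20 residues + gap)
or q = 65 (64 codons + gap) states.  Gap handling follows each method's
tradition: OMES/MI/MIp treat the gap as a full scoring state (the
summations run to q); DCA and the sparse inverse-covariance scorer drop
the gap as the gauge/reference state of a (q−1)-dimensional one-hot
encoding.

- **OMES** — Σ_ab (OBS_ab − EXP_ab)² on the weighted pair-count table,
  EXP the product-model expectation; raw counts, no pseudocount.
- **MI** — Σ_ab f_ab log[f_ab/(f_a f_b)] in natural log (the base only
  rescales rankings uniformly).  **MIp** subtracts the average product
  correction APC(i,j) = MI(i,·) MI(j,·) / MI̅ computed over all
  off-diagonal pairs.
- **mfDCA** — sequences reweighted at 80 % identity (weight 1/k for a
  sequence with k neighbours at ≥ 0.8 identity; Meff = Σ weights);
  frequencies pseudocounted with λ = Meff (data and prior mixed 1:1,
  with the pair-matrix diagonal blocks smoothed only on their diagonal
  so f(i,i,a,b) stays δ_ab f(i,a)); connected correlation matrix over
  q−1 states inverted to give couplings; per pair, a two-site model with
  fields fitted by iterative proportional scaling (tolerance 1e-4, max
  500 iterations) yields the direct distribution, whose mutual
  information is the direct information DI.
- **PSICOV-style** — weighted sample covariance of the one-hot encoding,
  shrunk toward the mean-variance identity in steps of 0.05 until
  positive definite (a uniform diagonal target also lifts the exactly
  singular directions of never-observed states, and shrinkage increases
  further if the solver still reports ill-conditioning), then
  graphical-lasso precision estimation at penalty ρ = 0.001; the
  pair score is the L1 norm of the (q−1)×(q−1) precision block, with APC
  optionally subtracted (the no-APC variant is labelled PSICOV*).  A
  diversity guard refuses alignments with Meff < 125 (the published
  tool applies such a threshold without stating its value; 125 is this
  package's choice, and the check can be disabled).

Both inverse-covariance scorers refuse problems with L·(q−1) > 20 000
unless overridden — the dense correlation matrix grows as its square.

## Evaluation protocol

Contacts come from structure under three definitions: Cβ–Cβ ≤ 8 Å (Cα
for glycine; a non-glycine residue with no Cβ falls back to Cα and is
counted), any heavy-atom pair ≤ 8 Å, and "physical" ≤ 3.5 Å.  Both
thresholds are inclusive.  Hydrogens are excluded; for alternate
conformations the highest-occupancy atom is kept.  Only pairs separated
by at least 5 positions in sequence count, for contacts and predictions
alike; under this reading a 100-residue chain offers T(T+1)/2 = 4560
candidate pairs (T = 95).

Alignment columns map to structure residues through a global pairwise
alignment (match +1, mismatch −1, gap open −5, extend −1 — the tooling
convention; the original protocol names its alignment software but not
its parameters).  Only identically matched positions are mapped, and a
mapping below 80 % domain coverage fails the inclusion rule.  Accuracy
at N is the fraction of true contacts among the N highest-ranked mapped
predictions; the AUC is the trapezoid of the accuracy-vs-N curve over
N = 1..L (L = domain length) by default — the published protocol does
not state its N range, so it is exposed as configuration — and the
improvement is 100·(AUC_combined − AUC_base)/AUC_base.  Per family, up
to 30 unique-sequence structures with the best resolution (ties broken
by identifier) are averaged so well-crystallised families are not
over-represented.

Significance over a family set uses two-sided tests on the per-family
improvement deltas: the exact binomial sign test on the counts, and the
Wilcoxon signed-rank test (exact enumeration for n ≤ 25 without tied
magnitudes, otherwise a normal approximation with tie and continuity
corrections).  Zero deltas are dropped; sidedness is configurable
because the original report does not state it.

## The synthetic-data generator

No public benchmark ships paired codon/amino-acid alignments with known
ground truth, so the generator makes the method's premise a measurable
property.  Sequences are drawn independently (no phylogeny — ancestry
confounds are out of scope for this generator) by Gibbs sampling from a
pairwise model over codon states; 50 burn-in plus 200 recorded sweeps,
final configuration kept per sequence.

Default study conditions: 30 columns, 2000 sequences.  Each site is
restricted to a repertoire of 4 amino acids (Dirichlet(4) field
weights) with 2 synonymous codons each; confound sites use amino acids
with ≥ 4 codons and keep 4 synonymous codons per amino acid, giving the
codon channel room to carry signal beyond translation.

- **Contact pairs** (default 26, the density of a real contact map at
  this length): coupling β_aa = 3.0 between translated amino acids via
  a random bijection — codon choice within an amino acid stays free, so
  the codon-level correlation of a contact is exactly its translated
  correlation.  Contact pairs avoid confound sites (a strong codon-level
  coupling on a shared site starves the contact coupling of signal) and
  the contact graph is degree-capped at 3.
- **Confound pairs** (default 6, never contacts, disjoint sites):
  coupling β_syn = 6.0 along a codon-level bijection.  In the default
  `aa_and_codon` mode the bijection starts amino-acid-respecting and a
  fraction (0.3) of its images is scrambled across amino-acid groups:
  the codon-level correlation stays maximal while only part of it
  survives translation, which reproduces the false-positive signature —
  amino-acid correlation strong enough to crack the top of the
  amino-acid-only ranking, codon correlation far in excess of it.  In
  `codon_only` mode each confound site carries a single amino acid and
  only the synonymous choice is coupled, so the translated columns are
  constant and the amino-acid signal is exactly zero.
- `confound_dissociation_check` verifies per confound pair that codon
  MI exceeds the 95th percentile of non-planted pairs, and (mode-
  dependent) that amino-acid MI is at or below the non-planted median
  (`codon_only`) or that the codon-minus-amino-acid MI excess exceeds
  the 95th percentile of the background excess (`aa_and_codon`).

The synthetic structure embeds the planted contacts geometrically:
single-atom residues (so all three contact definitions coincide and the
evaluation logic is isolated from geometry), contact pairs closer than
6 Å, every other pair at separation ≥ 5 farther than 9 Å, found by
L-BFGS on pure inequality penalties with random restarts.  Two graph
motifs are excluded during contact sampling because they cannot satisfy
these distances in 3-D: 4-cycles (two residues sharing two close
neighbours must lie in the same small lens yet sit far apart) and
5-cycles (realisable only in a sliver of configurations near the
regular pentagon).  Even so, not every dense random contact graph is
realisable, so family sampling redraws the planted-pair layout until
one embeds; the chain's contact map at 8 Å then equals the planted set
exactly.

What the generator does **not** emulate: phylogenetic correlation,
gaps, alignment errors, realistic amino-acid frequency profiles, or
indirect structural chains longer than the planted graph.  Passing
tests therefore demonstrate that the machinery behaves as specified on
data satisfying the model's premise, not that the improvement transfers
to any particular real protein family.

## Problem sizes and numerical choices

The end-to-end experiments run at desk scale: recovery checks at
L = 12, M = 1000 and the core-claim comparison on ten families at
L = 30, M = 2000, where codon-level DCA inverts a 1920×1920 correlation
matrix in seconds.  The two-site fit tolerance (1e-4), the DI floor at
0, the ε floor in the combined score, the shrinkage step (0.05) and the
embedding margins (0.3 Å inside the hard bounds) are fixed constants
chosen once; degenerate inputs (all-zero MI matrices, alignments with a
singular correlation matrix at λ = 0, chains without contacts) raise
explicit errors rather than returning silent zeros.

## Known limitations

- Mean-field DCA is an approximation; at the strong planted couplings
  used here its DI values are useful for ranking, not as calibrated
  interaction strengths.
- Codon-level PSICOV at realistic domain lengths exceeds the default
  memory guard; it is intended for short domains or subsampled columns.
- The α default grid tops out at 20.0; methods whose improvement is
  still rising there (as the published PSICOV* optimum's flatness
  suggests) need a wider grid.
- Sequence reweighting for codon alignments uses codon-level identity,
  computed independently of the amino-acid weighting; whether the
  original analysis did the same is unstated in its description.
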