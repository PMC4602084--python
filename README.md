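# codoncma — codon-aware correlated mutation analysis

Correlated mutation analysis (CMA) predicts residue–residue contacts by
ranking column pairs of a protein multiple sequence alignment (MSA) by
their coevolution score.  Its classic failure mode is the pair that is
strongly correlated for reasons other than a structural contact —
nucleic-acid-level selection or shared ancestry.  Such pairs tend to
betray themselves at the **codon** level: a correlation that persists
among synonymous codons cannot be explained by selection on the protein
structure.

`codoncma` implements contact prediction that uses both channels.  Every
scorer runs on the amino-acid alignment (21 states) and on the matching
codon alignment (65 states, built by threading coding sequences onto the
protein alignment), and the two score matrices are combined per pair as

    S  =  S_AA^α / S_C

so that pairs strong at the amino-acid level but weak at the codon level
— the signature of a real contact — rise in rank.  The exponent α is
fitted per base method by maximising the median percent AUC improvement
of the accuracy-vs-number-of-predictions curve over a family set
(defaults: α = 2.5 for DCA and MI, 1.7 for OMES, 11.2 for the
no-APC PSICOV variant).

The package is a library with:

- **msa / alphabets** — FASTA and Stockholm I/O, codon-MSA construction
  from unaligned CDS (tranalign-style), identity-based sequence
  reweighting (Meff), pseudocounted frequency models;
- **scores / dca / psicov** — alphabet-generic OMES, mutual information,
  average product correction (MIp), mean-field direct coupling analysis
  (direct information), and an L1-regularised sparse inverse-covariance
  scorer with optional APC;
- **combine** — the combined score, α grid fitting, and random-split
  cross-validation of α;
- **structure / evaluate** — PDB/mmCIF chains, contact maps under three
  definitions (Cβ ≤ 8 Å with Cα for glycine, any-heavy-atom ≤ 8 Å,
  physical ≤ 3.5 Å), alignment-column↔residue mapping with an 80 %
  coverage rule, accuracy curves, AUC improvement, per-family averaging
  capped at 30 best-resolution structures, and contact-threshold sweeps;
- **stats** — exact sign test and Wilcoxon signed-rank test on
  per-family improvements;
- **simulate** — a seeded Gibbs sampler over codon states that plants
  amino-acid-level couplings on true contacts and codon-level couplings
  on non-contact confound pairs, plus a geometric embedding that turns
  the planted contacts into a synthetic structure.

## Worked example

`examples/03_combined_score.py` runs the method end to end on one
synthetic family (30 columns, 2000 coding sequences, 26 planted
contacts, 6 codon-level confounds):

```
family: 30 columns, 2000 sequences, 26 planted contacts, 6 codon-level confounds
top-L precision, amino acids only : 0.800
top-L precision, combined score   : 0.867
confounds in top L, amino acids   : 6
confounds in top L, combined      : 4
AUC improvement                   : 28.1%
```

Amino-acid-only DCA ranks all six confound pairs among its top-30
predictions, displacing true contacts; dividing by the codon score
demotes them and the precision of the top-L list rises.  The other
examples cover the classical scorers (`01`), codon-MSA construction
(`02`), and α fitting with cross-validation (`04`).

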