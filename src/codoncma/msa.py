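"""Multiple sequence alignments as integer state matrices.

Reading/writing (FASTA and Stockholm via Biopython), threading of
unaligned coding sequences onto a protein alignment to build a codon
MSA, and identity-based sequence reweighting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import AA_ALPHABET, CODON_ALPHABET, Alphabet, GeneticCode, STANDARD_CODE

__all__ = [
    "Msa",
    "read_msa",
    "write_msa",
    "read_fasta_records",
    "build_codon_msa",
    "translate_msa",
    "compute_weights",
]

_VALID_NUCS = frozenset("ACGT")


@dataclass
class Msa:
    """M x L alignment of state indices over an :class:`Alphabet`.

    ``weights`` (optional, per sequence, values in (0, 1]) come from
    identity-based reweighting; their sum is the effective number of
    sequences Meff.
    """

    states: np.ndarray
    ids: list[str]
    alphabet: Alphabet
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[0] < 1 or self.states.shape[1] < 1:
            raise ValueError("states must be an M x L matrix with M, L >= 1")
        if len(self.ids) != self.states.shape[0]:
            raise ValueError("one id per sequence required")
        if self.states.min() < 0 or self.states.max() >= self.alphabet.size:
            raise ValueError("state index out of range for alphabet")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.states.shape[0],):
                raise ValueError("weights must have one entry per sequence")
            if np.any(self.weights <= 0) or np.any(self.weights > 1):
                raise ValueError("weights must lie in (0, 1]")

    @property
    def n_sequences(self) -> int:
        return self.states.shape[0]

    @property
    def n_columns(self) -> int:
        return self.states.shape[1]

    @property
    def meff(self) -> float:
        """Effective sequence number: sum of weights (M if unweighted)."""
        if self.weights is None:
            return float(self.n_sequences)
        return float(self.weights.sum())

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.n_sequences)
        return self.weights

    def sequence_str(self, row: int) -> str:
        """Row as a token string (gapped)."""
        return "".join(self.alphabet.symbols[s] for s in self.states[row])

    def ungapped_sequence(self, row: int) -> str:
        gap = self.alphabet.gap_state
        return "".join(
            self.alphabet.symbols[s] for s in self.states[row] if s != gap
        )


def _tokenize(seq: str, alphabet: Alphabet, record_id: str) -> list[int]:
    w = alphabet.token_width
    if len(seq) % w != 0:
        raise ValueError(
            f"record '{record_id}': sequence length {len(seq)} not divisible "
            f"by token width {w}"
        )
    out = []
    for k in range(0, len(seq), w):
        tok = seq[k : k + w]
        if w == 3:
            # gaps in codon alignments appear as '---'; any ambiguous or
            # partially gapped triplet conservatively becomes the gap state
            if not _VALID_NUCS.issuperset(tok):
                out.append(alphabet.gap_state)
                continue
        out.append(alphabet.index(tok))
    return out


def read_msa(path: str | os.PathLike, fmt: str, alphabet: Alphabet) -> Msa:
    """Read an aligned FASTA or Stockholm file into an :class:`Msa`.

    Tokens outside the alphabet (unknown residues such as ``X``,
    ambiguous codons) are mapped to the gap state.  Raises on ragged
    alignments (naming the offending record) and on empty files.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format: {fmt!r}")
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    length = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(
                f"ragged alignment: record '{rec.id}' has length "
                f"{len(rec.seq)}, expected {length}"
            )
    rows = [_tokenize(str(rec.seq).upper(), alphabet, rec.id) for rec in records]
    return Msa(np.array(rows), [rec.id for rec in records], alphabet)


def write_msa(msa: Msa, path: str | os.PathLike, fmt: str = "fasta") -> None:
    """Write an alignment back out (FASTA or Stockholm)."""
    records = [
        SeqRecord(Seq(msa.sequence_str(s)), id=msa.ids[s], description="")
        for s in range(msa.n_sequences)
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


def read_fasta_records(path: str | os.PathLike) -> dict[str, str]:
    """Unaligned FASTA -> {id: sequence}, e.g. coding sequences for threading."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences found in {path}")
    return out


def translate_msa(codon_msa: Msa, code: GeneticCode = STANDARD_CODE) -> Msa:
    """Column-wise translation of a codon MSA to the amino-acid alphabet.

    Stop codons and codon gaps both map to the amino-acid gap state.
    """
    if codon_msa.alphabet is not CODON_ALPHABET:
        raise ValueError("translate_msa expects a codon-alphabet MSA")
    lut = np.empty(CODON_ALPHABET.size, dtype=np.int64)
    for i, codon in enumerate(CODON_ALPHABET.symbols):
        if codon == CODON_ALPHABET.gap_token:
            lut[i] = AA_ALPHABET.gap_state
        else:
            aa = code.translate_codon(codon)
            lut[i] = AA_ALPHABET.gap_state if aa == "*" else AA_ALPHABET.index(aa)
    return Msa(lut[codon_msa.states], list(codon_msa.ids), AA_ALPHABET)


def build_codon_msa(
    protein_msa: Msa,
    cds: dict[str, str],
    code: GeneticCode = STANDARD_CODE,
) -> Msa:
    """Thread unaligned coding sequences onto a protein alignment.

    Mirrors tranalign-style back-translation: each coding sequence is cut
    into codons, verified to translate to the ungapped protein row, and
    the codons are placed under the non-gap columns of that row; protein
    gap columns become codon gap states.  One trailing stop codon, if
    present, is stripped before verification.
    """
    if protein_msa.alphabet is not AA_ALPHABET:
        raise ValueError("protein_msa must use the amino-acid alphabet")
    missing = [i for i in protein_msa.ids if i not in cds]
    if missing:
        raise KeyError(f"missing coding sequence for ids: {', '.join(missing)}")

    gap = AA_ALPHABET.gap_state
    out = np.full(protein_msa.states.shape, CODON_ALPHABET.gap_state, dtype=np.int64)
    for s, rid in enumerate(protein_msa.ids):
        seq = cds[rid]
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS '{rid}': length {len(seq)} not divisible by 3")
        codons = [seq[k : k + 3] for k in range(0, len(seq), 3)]
        if codons and _VALID_NUCS.issuperset(codons[-1]) and code.is_stop(codons[-1]):
            codons = codons[:-1]
        protein = protein_msa.ungapped_sequence(s)
        if len(codons) != len(protein):
            raise ValueError(
                f"CDS '{rid}': {len(codons)} codons but protein row has "
                f"{len(protein)} residues"
            )
        for pos, (codon, aa) in enumerate(zip(codons, protein)):
            translated = (
                code.translate_codon(codon) if _VALID_NUCS.issuperset(codon) else None
            )
            if translated is not None and translated != aa:
                raise ValueError(
                    f"CDS '{rid}': translation mismatch at ungapped position "
                    f"{pos + 1} (codon {codon} -> {translated}, protein {aa})"
                )
        cols = np.flatnonzero(protein_msa.states[s] != gap)
        out[s, cols] = [CODON_ALPHABET.index(c) for c in codons]
    return Msa(out, list(protein_msa.ids), CODON_ALPHABET)


def compute_weights(msa: Msa, identity_threshold: float = 0.8) -> tuple[np.ndarray, float]:
    """Identity-based sequence reweighting.

    The weight of sequence s is 1 / (number of sequences, s included,
    whose fractional identity with s over all columns is >= the
    threshold); Meff is the sum of weights.  This is the reweighting
    step of the mean-field direct-coupling recipe.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    states = msa.states
    m, length = states.shape
    counts = np.zeros(m, dtype=np.int64)
    # chunked pairwise identity to bound memory at ~chunk * M * L bytes
    chunk = max(1, int(2e8 // (m * length + 1)))
    for start in range(0, m, chunk):
        block = states[start : start + chunk]
        ident = (block[:, None, :] == states[None, :, :]).mean(axis=2)
        counts[start : start + chunk] = (ident >= identity_threshold).sum(axis=1)
    weights = 1.0 / counts
    return weights, float(weights.sum())
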