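"""Finite state alphabets shared by every scorer.

Two alphabets matter in practice: the 21-state amino-acid alphabet
(20 residues + gap) and the 65-state codon alphabet (64 trinucleotides +
gap).  All multiple sequence alignments are stored as integer state
matrices over one of these, so scorers are alphabet-generic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "Alphabet",
    "GeneticCode",
    "AA_ALPHABET",
    "CODON_ALPHABET",
    "STANDARD_CODE",
]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_NUCS = "TCAG"


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set with a gap token.

    Symbols are single letters for amino acids and trinucleotide strings
    for codons; the gap token is a first-class state, so ``size`` counts
    it (q = 21 for amino acids, q = 65 for codons).
    """

    symbols: tuple[str, ...]
    gap_token: str = GAP
    name: str = "custom"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.gap_token not in self.symbols:
            raise ValueError("gap_token must be a member of symbols")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def gap_state(self) -> int:
        return self._index[self.gap_token]

    @property
    def token_width(self) -> int:
        """Character width of one token (1 for amino acids, 3 for codons)."""
        return len(self.symbols[0])

    def index(self, token: str) -> int:
        """State index of ``token``; unknown tokens map to the gap state."""
        return self._index.get(token, self.gap_state)

    def __len__(self) -> int:
        return self.size

    def __contains__(self, token: str) -> bool:
        return token in self._index


def _codon_symbols() -> tuple[str, ...]:
    return tuple("".join(c) for c in itertools.product(_NUCS, repeat=3))


#: 20 residues + gap; gap is the last state (index 20).
AA_ALPHABET = Alphabet(tuple(AA_LETTERS) + (GAP,), name="aa")

#: 64 codons + gap; stop codons are retained as ordinary states.
CODON_ALPHABET = Alphabet(_codon_symbols() + ("-" * 3,), gap_token="-" * 3, name="codon")


@dataclass(frozen=True)
class GeneticCode:
    """Total map from the 64 codons to amino-acid letters ('*' for stop)."""

    table: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.table) != set(_codon_symbols()):
            raise ValueError("genetic code must cover exactly the 64 codons")

    def translate_codon(self, codon: str) -> str:
        return self.table[codon]

    def translate(self, cds: str) -> str:
        """Translate an in-frame nucleotide string (length divisible by 3)."""
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        return "".join(self.table[cds[k : k + 3]] for k in range(0, len(cds), 3))

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == "*"

    @classmethod
    def standard(cls) -> "GeneticCode":
        from Bio.Data import CodonTable

        bio = CodonTable.unambiguous_dna_by_id[1]
        table = {c: bio.forward_table.get(c, "*") for c in _codon_symbols()}
        return cls(table)


STANDARD_CODE = GeneticCode.standard()
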