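import numpy as np
import pytest

from codoncma import AA_ALPHABET, CODON_ALPHABET, Msa


def make_aa_msa(rows: list[str], ids=None) -> Msa:
    """Build an amino-acid Msa from one-letter strings."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    states = np.array([[AA_ALPHABET.index(c) for c in row] for row in rows])
    return Msa(states, ids, AA_ALPHABET)


def make_codon_msa(rows: list[list[str]], ids=None) -> Msa:
    """Build a codon Msa from lists of triplet tokens."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    states = np.array([[CODON_ALPHABET.index(c) for c in row] for row in rows])
    return Msa(states, ids, CODON_ALPHABET)


@pytest.fixture
def random_aa_msa():
    """Seeded random 20x8 amino-acid alignment without gaps."""
    rng = np.random.default_rng(1234)
    states = rng.integers(0, 20, size=(20, 8))
    return Msa(states, [f"s{i}" for i in range(20)], AA_ALPHABET)
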