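"""Thread coding sequences onto a protein alignment to build a codon MSA.

Shows the tranalign-style construction: each unaligned CDS is cut into
codons, checked against its translated protein row, and placed under the
alignment columns; protein gaps become codon gaps.
"""

from codoncma import CODON_ALPHABET, build_codon_msa, read_msa, translate_msa
from codoncma.alphabets import AA_ALPHABET
from codoncma.msa import Msa

import numpy as np

rows = ["MK-LV", "M-ALV", "MKAL-"]
cds = {
    "a": "ATGAAACTTGTT",        # MKLV
    "b": "ATGGCGCTGGTCTAA",     # MALV + stop (stripped)
    "c": "ATGAAAGCACTC",        # MKAL
}
states = np.array([[AA_ALPHABET.index(c) for c in r] for r in rows])
protein = Msa(states, list("abc"), AA_ALPHABET)

codon = build_codon_msa(protein, cds)
for s in range(codon.n_sequences):
    toks = [CODON_ALPHABET.symbols[x] for x in codon.states[s]]
    print(f"{codon.ids[s]}: {' '.join(toks)}")

back = translate_msa(codon)
print("translates back to the protein alignment:",
      bool(np.array_equal(back.states, protein.states)))
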