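"""Protein-structure side of the evaluation: chains, contact maps, mapping.

A :class:`StructureChain` keeps, per residue, the Cβ coordinate (Cα for
glycine) and all heavy-atom coordinates, which is everything the three
contact definitions need:

``cbeta``     Cβ–Cβ distance <= threshold (classically 8 Å),
``all_atom``  any heavy-atom pair <= threshold,
``physical``  any heavy-atom pair <= 3.5 Å.

Only residue pairs separated by at least ``min_separation`` positions in
sequence (default 5) count as contacts or predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "StructureChain",
    "ContactMap",
    "ColumnMapping",
    "contact_map",
    "physical_contact_fraction",
    "map_columns_to_structure",
    "n_candidate_pairs",
    "read_structure_chain",
    "write_chain_pdb",
]

PHYSICAL_THRESHOLD = 3.5  # Å, inclusive
DEFAULT_CONTACT_THRESHOLD = 8.0  # Å, inclusive
DEFAULT_MIN_SEPARATION = 5

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


@dataclass
class StructureChain:
    """One polypeptide chain reduced to evaluation-relevant coordinates."""

    id: str
    sequence: str  # one-letter codes, X for nonstandard residues
    cb_coords: np.ndarray  # (L, 3); NaN rows mark residues with no usable atom
    heavy_coords: list[np.ndarray]  # per residue, (n_atoms, 3) heavy atoms
    resolution: float | None = None
    n_cb_fallback: int = 0  # non-glycine residues where Cα stood in for Cβ

    def __post_init__(self) -> None:
        self.cb_coords = np.asarray(self.cb_coords, dtype=float)
        if len(self.sequence) != self.cb_coords.shape[0] or len(self.sequence) != len(
            self.heavy_coords
        ):
            raise ValueError("sequence length must match residue count")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass
class ContactMap:
    """Symmetric boolean contact matrix under a named definition."""

    contacts: np.ndarray
    definition: str
    threshold: float
    min_separation: int = DEFAULT_MIN_SEPARATION
    n_excluded_residues: int = 0  # residues without coordinates

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=bool)
        if not np.array_equal(self.contacts, self.contacts.T):
            raise ValueError("contact matrix must be symmetric")
        if np.any(np.diag(self.contacts)):
            raise ValueError("no self-contacts allowed")

    @property
    def n_residues(self) -> int:
        return self.contacts.shape[0]

    @property
    def n_contacts(self) -> int:
        return int(np.triu(self.contacts).sum())

    def pairs(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.contacts))
        return list(zip(ii.tolist(), jj.tolist()))

    def write_pairs(self, path) -> None:
        with open(path, "w") as fh:
            for i, j in self.pairs():
                fh.write(f"{i + 1}\t{j + 1}\n")


@dataclass
class ColumnMapping:
    """Order-preserving map from alignment columns to structure residues."""

    col_to_res: dict[int, int]
    coverage: float
    passes_inclusion: bool = field(init=False)

    def __post_init__(self) -> None:
        cols = sorted(self.col_to_res)
        res = [self.col_to_res[c] for c in cols]
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ValueError("mapping must be strictly increasing")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must lie in [0, 1]")
        # the benchmark inclusion rule: >= 80% of domain positions mapped
        self.passes_inclusion = self.coverage >= 0.8

    @classmethod
    def identity(cls, length: int) -> "ColumnMapping":
        return cls({i: i for i in range(length)}, 1.0)


def _separation_mask(length: int, min_separation: int) -> np.ndarray:
    idx = np.arange(length)
    return np.abs(idx[:, None] - idx[None, :]) >= min_separation


def contact_map(
    chain: StructureChain,
    definition: str = "cbeta",
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactMap:
    """Contact map of a chain under one of the three definitions.

    Thresholds are inclusive.  Residues with no resolved heavy atoms are
    excluded from all pairs and counted in ``n_excluded_residues``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = chain.n_residues
    if definition == "cbeta":
        coords = chain.cb_coords
        valid = ~np.isnan(coords).any(axis=1)
        d = cdist(coords[valid], coords[valid])
        mat = np.zeros((n, n), dtype=bool)
        vi = np.flatnonzero(valid)
        mat[np.ix_(vi, vi)] = d <= threshold
    elif definition in ("all_atom", "physical"):
        if definition == "physical":
            threshold = PHYSICAL_THRESHOLD
        valid = np.array([len(a) > 0 for a in chain.heavy_coords])
        vi = np.flatnonzero(valid)
        atoms = np.concatenate([chain.heavy_coords[i] for i in vi], axis=0)
        labels = np.concatenate(
            [np.full(len(chain.heavy_coords[i]), k) for k, i in enumerate(vi)]
        )
        d = cdist(atoms, atoms)
        close = d <= threshold
        sub = np.zeros((len(vi), len(vi)), dtype=bool)
        np.logical_or.at(sub, (labels[:, None], labels[None, :]), close)
        mat = np.zeros((n, n), dtype=bool)
        mat[np.ix_(vi, vi)] = sub
    else:
        raise ValueError(f"unknown contact definition: {definition!r}")

    mat &= _separation_mask(n, min_separation)
    np.fill_diagonal(mat, False)
    mat |= mat.T
    return ContactMap(
        mat, definition, threshold, min_separation, n_excluded_residues=int((~valid).sum())
    )


def physical_contact_fraction(
    chain: StructureChain,
    definition: str = "cbeta",
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> float:
    """Fraction of contacts (under ``definition``) that are physical.

    Physical means at least one heavy-atom pair within 3.5 Å.  Raises on
    chains with no contacts under the chosen definition.
    """
    base = contact_map(chain, definition, threshold, min_separation)
    if base.n_contacts == 0:
        raise ValueError("no contacts under the chosen definition; fraction undefined")
    phys = contact_map(chain, "physical", min_separation=min_separation)
    both = base.contacts & phys.contacts
    return float(np.triu(both).sum() / base.n_contacts)


def map_columns_to_structure(domain_seq: str, chain: StructureChain) -> ColumnMapping:
    """Global alignment of the domain sequence to the chain's ATOM sequence.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -1.  Only
    identically matched positions enter the mapping; coverage is the
    fraction of domain positions so mapped, and mappings below 80%
    coverage fail the benchmark's inclusion rule (flagged, not fatal —
    the caller decides).
    """
    if not domain_seq or not chain.sequence:
        raise ValueError("both sequences must be nonempty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    a = domain_seq.upper()
    b = chain.sequence.upper()
    aln = aligner.align(a, b)[0]
    col_to_res: dict[int, int] = {}
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            if a[a_start + off] == b[b_start + off]:
                col_to_res[a_start + off] = b_start + off
    coverage = len(col_to_res) / len(a)
    return ColumnMapping(col_to_res, coverage)


def n_candidate_pairs(n: int, min_separation: int = DEFAULT_MIN_SEPARATION) -> int:
    """Number of residue pairs (i < j) with j - i >= min_separation.

    For a 100-residue protein at separation 5 this is 4560 — the pool of
    potential contacts a predictor ranks.
    """
    if n < 0:
        raise ValueError("chain length must be nonnegative")
    t = max(0, n - min_separation)
    return t * (t + 1) // 2


# ---------------------------------------------------------------------------
# coordinate file I/O (PDB and mmCIF, via biotite)


def _chain_from_atoms(atoms, chain_id: str, resolution: float | None) -> StructureChain:
    import biotite.structure as struc

    atoms = atoms[struc.filter_amino_acids(atoms) & (atoms.element != "H")]
    if atoms.array_length() == 0:
        raise ValueError(f"chain {chain_id!r}: no protein heavy atoms found")
    sequence = []
    cb = []
    heavy = []
    n_fallback = 0
    for res in struc.residue_iter(atoms):
        name = res.res_name[0]
        one = _AA3TO1.get(name, "X")
        sequence.append(one)
        heavy.append(np.array(res.coord, dtype=float))
        target = "CA" if one == "G" else "CB"
        sel = res[res.atom_name == target]
        if sel.array_length() == 0 and target == "CB":
            sel = res[res.atom_name == "CA"]
            if sel.array_length() > 0:
                n_fallback += 1
        if sel.array_length() == 0:
            cb.append(np.full(3, np.nan))
        else:
            cb.append(np.array(sel.coord[0], dtype=float))
    return StructureChain(
        id=chain_id,
        sequence="".join(sequence),
        cb_coords=np.array(cb),
        heavy_coords=heavy,
        resolution=resolution,
        n_cb_fallback=n_fallback,
    )


def read_structure_chain(path, chain_id: str | None = None) -> StructureChain:
    """Read one chain from a PDB or mmCIF file.

    Keeps the highest-occupancy alternate conformer, drops hydrogens and
    hetero records, and defaults to the first chain in the file.
    """
    path = str(path)
    if path.endswith((".cif", ".mmcif")):
        import biotite.structure.io.pdbx as pdbx

        f = pdbx.CIFFile.read(path)
        atoms = pdbx.get_structure(f, model=1, altloc="occupancy")
    else:
        import biotite.structure.io.pdb as pdbio

        f = pdbio.PDBFile.read(path)
        atoms = f.get_structure(model=1, altloc="occupancy")
    atoms = atoms[~atoms.hetero]
    cid = chain_id if chain_id is not None else atoms.chain_id[0]
    sel = atoms[atoms.chain_id == cid]
    if sel.array_length() == 0:
        raise ValueError(f"chain {cid!r} not found in {path}")
    return _chain_from_atoms(sel, cid, resolution=None)


def write_chain_pdb(chain: StructureChain, path) -> None:
    """Write a chain's heavy atoms as a minimal PDB file."""
    with open(path, "w") as fh:
        serial = 1
        for i, (aa, res_atoms) in enumerate(zip(chain.sequence, chain.heavy_coords)):
            res3 = _AA1TO3.get(aa, "UNK")
            for k, (x, y, z) in enumerate(res_atoms):
                name = ("CA" if aa == "G" else "CB") if k == 0 else f"X{k}"
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}{res3:>4s} A{i + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
        fh.write("END\n")
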