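"""Seeded generator of paired codon/amino-acid alignments with planted signal.

Sequences are drawn by Gibbs sampling from a pairwise (Potts-like) model
over codon states.  Two kinds of couplings are planted:

* ``aa_coupled`` pairs — the coupling depends on codon states only
  through their translated amino acids, so the correlation is visible in
  the amino-acid alignment.  These pairs are true contacts and the
  synthetic structure realises them geometrically.
* ``codon_confound`` pairs — the coupling acts on codon identity.  In
  the default ``aa_and_codon`` mode it follows a full codon bijection,
  producing strong correlation at both the amino-acid and the codon
  level (the classic false-positive signature of nucleic-acid-level
  selection or shared ancestry); in ``codon_only`` mode each site is
  fixed to a single amino acid and only the choice among synonymous
  codons is coupled, so the translated columns carry no signal at all.
  Confound pairs are never contacts.

All remaining sites are independent.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alphabets import AA_ALPHABET, CODON_ALPHABET, STANDARD_CODE
from .msa import Msa, translate_msa
from .structure import StructureChain

__all__ = [
    "SimulationConfig",
    "PlantedFamily",
    "sample_family",
    "confound_dissociation_check",
    "make_synthetic_chain",
    "export_family",
]

# amino acids by synonymous-codon count under the standard code
_AA_BY_CODON_COUNT: dict[str, list[str]] = {}
for _codon in CODON_ALPHABET.symbols[:-1]:
    _aa = STANDARD_CODE.translate_codon(_codon)
    if _aa != "*":
        _AA_BY_CODON_COUNT.setdefault(_aa, []).append(_codon)
_MULTI_CODON_AAS = sorted(a for a, c in _AA_BY_CODON_COUNT.items() if len(c) >= 2)
_RICH_CODON_AAS = sorted(a for a, c in _AA_BY_CODON_COUNT.items() if len(c) >= 4)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic family.

    Defaults are the desk-scale conditions used throughout: a 30-column
    domain with 2000 sequences, a contact-dense topology (26 coupled
    contact pairs) plus 6 codon-level confound pairs, and couplings
    strong enough that both signals are individually recoverable.
    """

    n_columns: int = 30
    n_sequences: int = 2000
    n_contact: int = 26
    n_confound: int = 6
    beta_aa: float = 3.0
    beta_syn: float = 6.0
    confound_aa_scramble: float = 0.3
    field_concentration: float = 4.0
    sweeps: int = 200
    burn_in: int = 50
    seed: int = 0
    confound_mode: str = "aa_and_codon"  # or "codon_only"
    aas_per_site: int = 4
    syn_per_contact_aa: int = 2
    syn_per_confound_aa: int = 4
    min_separation: int = 5
    max_contact_degree: int = 3

    def __post_init__(self) -> None:
        if self.n_columns < 12 or self.n_sequences < 50:
            raise ValueError("need at least 12 columns and 50 sequences")
        if self.confound_mode not in ("aa_and_codon", "codon_only"):
            raise ValueError(f"unknown confound_mode: {self.confound_mode!r}")
        n_contact_sites = self.n_columns - 2 * self.n_confound
        if n_contact_sites < 0:
            raise ValueError("not enough sites for the confound pairs")
        if self.n_contact > n_contact_sites * self.max_contact_degree // 2:
            raise ValueError("contact pair count infeasible at this degree cap")


@dataclass
class PlantedFamily:
    """One synthetic family with its complete ground truth."""

    codon_msa: Msa
    protein_msa: Msa
    true_contacts: frozenset[tuple[int, int]]
    aa_coupled: frozenset[tuple[int, int]]
    codon_confound: frozenset[tuple[int, int]]
    chain: StructureChain
    seed: int
    config: SimulationConfig = field(repr=False, default=None)


def _place_pairs(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Sample disjoint confound pairs and degree-capped contact pairs.

    All pairs satisfy j - i >= min_separation.  Confound pairs occupy
    disjoint site pairs, and contact pairs avoid confound sites entirely
    so that a strong codon-level coupling never starves a contact
    coupling of signal on a shared site; the contact graph is degree-
    capped so it remains geometrically embeddable.
    """
    length, sep = cfg.n_columns, cfg.min_separation
    for _ in range(200):
        sites = list(range(length))
        rng.shuffle(sites)
        confounds: list[tuple[int, int]] = []
        used: set[int] = set()
        pool = sites.copy()
        ok = True
        for _ in range(cfg.n_confound):
            placed = False
            for a in pool:
                if a in used:
                    continue
                partners = [b for b in pool if b not in used and abs(b - a) >= sep]
                if partners:
                    b = partners[int(rng.integers(len(partners)))]
                    confounds.append((min(a, b), max(a, b)))
                    used.update((a, b))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        contact_sites = [s for s in range(length) if s not in used]
        candidates = [
            (i, j)
            for k, i in enumerate(contact_sites)
            for j in contact_sites[k + 1 :]
            if j - i >= sep
        ]
        if len(candidates) < cfg.n_contact:
            continue
        order = rng.permutation(len(candidates))
        degree = dict.fromkeys(contact_sites, 0)
        adjacency: dict[int, set[int]] = {s: set() for s in contact_sites}
        contacts: list[tuple[int, int]] = []
        if cfg.n_contact == 0:
            return [], sorted(confounds)
        for idx in order:
            i, j = candidates[idx]
            if degree[i] >= cfg.max_contact_degree or degree[j] >= cfg.max_contact_degree:
                continue
            # 4-cycles cannot satisfy contacts < 6 A with non-contacts > 9 A
            # in 3-D (two nodes sharing two close neighbours must sit in the
            # same small lens yet far apart) and 5-cycles only barely can
            # (regular pentagon, diagonal 1.618x side), so reject edges
            # closing either: a new C4/C5 through edge (i, j) means a path
            # of length 3 or 4 already joins i and j.  Triangles stay
            # allowed — three mutually close residues embed trivially.
            n_i, n_j = adjacency[i], adjacency[j]
            if any((adjacency[a] & n_j) - {i} for a in n_i if a != j):
                continue
            if any(
                (adjacency[a] & adjacency[c]) - {i, j}
                for a in n_i
                if a != j
                for c in n_j
                if c != i and c != a
            ):
                continue
            contacts.append((i, j))
            adjacency[i].add(j)
            adjacency[j].add(i)
            degree[i] += 1
            degree[j] += 1
            if len(contacts) == cfg.n_contact:
                break
        if len(contacts) == cfg.n_contact:
            return sorted(contacts), sorted(confounds)
    raise RuntimeError("could not place planted pairs; config infeasible")


class _SiteModel:
    """Per-site codon repertoire with field log-weights."""

    def __init__(
        self, aas: list[str], syn: int, rng: np.random.Generator,
        concentration: float = 4.0,
    ):
        self.aas = aas
        self.codons: list[str] = []
        self.aa_index: list[int] = []  # repertoire-aa index per codon
        self.syn_rank: list[int] = []
        for k, aa in enumerate(aas):
            pool = list(_AA_BY_CODON_COUNT[aa])
            picked = [pool[t] for t in rng.choice(len(pool), size=syn, replace=False)]
            for r, codon in enumerate(sorted(picked)):
                self.codons.append(codon)
                self.aa_index.append(k)
                self.syn_rank.append(r)
        weights = rng.dirichlet(np.full(len(aas), concentration))
        self.h = np.log(weights[self.aa_index] / syn)
        self.aa_index = np.array(self.aa_index)
        self.syn_rank = np.array(self.syn_rank)
        self.global_states = np.array(
            [CODON_ALPHABET.index(c) for c in self.codons], dtype=np.int64
        )

    @property
    def n_codons(self) -> int:
        return len(self.codons)


def _gibbs_sample(
    rng: np.random.Generator,
    sites: list[_SiteModel],
    couplings: dict[tuple[int, int], np.ndarray],
    m: int,
    n_sweeps: int,
) -> list[np.ndarray]:
    """Independent Gibbs chains for the M sequences; returns local states."""
    length = len(sites)
    neighbours: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(length)}
    for (i, j), jmat in couplings.items():
        neighbours[i].append((j, jmat))
        neighbours[j].append((i, jmat.T))
    # initialise from the single-site fields
    states = []
    for site in sites:
        p = np.exp(site.h)
        p /= p.sum()
        states.append(rng.choice(site.n_codons, size=m, p=p))
    for _ in range(n_sweeps):
        for i, site in enumerate(sites):
            logits = np.broadcast_to(site.h, (m, site.n_codons)).copy()
            for j, jmat in neighbours[i]:
                logits += jmat.T[states[j]]
            gumbel = rng.gumbel(size=logits.shape)
            states[i] = np.argmax(logits + gumbel, axis=1)
    return states


def sample_family(cfg: SimulationConfig) -> PlantedFamily:
    """Draw one planted family under the configured study conditions."""
    rng = np.random.default_rng(cfg.seed)
    # sample planted-pair graphs until one admits a geometric embedding;
    # dense degree-3 contact graphs are not all realisable under the
    # contact/non-contact distance constraints
    chain = None
    for _ in range(150):
        contacts, confounds = _place_pairs(rng, cfg)
        try:
            chain = make_synthetic_chain(
                set(contacts),
                cfg.n_columns,
                seed=int(rng.integers(2**31 - 1)),
                min_separation=cfg.min_separation,
                max_retries=10,
            )
            break
        except RuntimeError:
            continue
    if chain is None:
        raise RuntimeError(
            "no embeddable planted-pair layout found after 150 draws; "
            "sparsify the contact configuration"
        )
    confound_sites = {s for p in confounds for s in p}

    sites: list[_SiteModel] = []
    for i in range(cfg.n_columns):
        if i in confound_sites:
            if cfg.confound_mode == "codon_only":
                aas = [
                    _RICH_CODON_AAS[int(rng.integers(len(_RICH_CODON_AAS)))]
                ]
            else:
                aas = [
                    _RICH_CODON_AAS[t]
                    for t in rng.choice(
                        len(_RICH_CODON_AAS), size=cfg.aas_per_site, replace=False
                    )
                ]
            sites.append(
                _SiteModel(aas, cfg.syn_per_confound_aa, rng, cfg.field_concentration)
            )
        else:
            aas = [
                _MULTI_CODON_AAS[t]
                for t in rng.choice(
                    len(_MULTI_CODON_AAS), size=cfg.aas_per_site, replace=False
                )
            ]
            sites.append(
                _SiteModel(aas, cfg.syn_per_contact_aa, rng, cfg.field_concentration)
            )

    couplings: dict[tuple[int, int], np.ndarray] = {}
    for i, j in contacts:
        si, sj = sites[i], sites[j]
        perm = rng.permutation(len(si.aas))
        jmat = np.where(
            perm[si.aa_index][:, None] == sj.aa_index[None, :], cfg.beta_aa, 0.0
        )
        couplings[(i, j)] = jmat
    for i, j in confounds:
        si, sj = sites[i], sites[j]
        # codon-level bijection: start amino-acid-respecting, then scramble
        # a fraction of the images across amino-acid groups.  The bijection
        # keeps the codon-level correlation maximal at strong beta_syn while
        # the scramble controls how much of it survives translation.
        image = np.empty(si.n_codons, dtype=int)
        if cfg.confound_mode == "codon_only":
            # single amino acid per site: pure synonymous-choice coupling
            image[:] = rng.permutation(si.n_codons)
        else:
            aa_perm = rng.permutation(len(si.aas))
            for k in range(len(si.aas)):
                syn_perm = rng.permutation(cfg.syn_per_confound_aa)
                src = np.flatnonzero(si.aa_index == k)
                dst = np.flatnonzero(sj.aa_index == aa_perm[k])
                image[src] = dst[syn_perm]
            n_scramble = int(round(cfg.confound_aa_scramble * si.n_codons))
            if n_scramble >= 2:
                picked = rng.choice(si.n_codons, size=n_scramble, replace=False)
                image[picked] = image[np.roll(picked, 1)]
        jmat = np.zeros((si.n_codons, sj.n_codons))
        jmat[np.arange(si.n_codons), image] = cfg.beta_syn
        couplings[(i, j)] = jmat

    local = _gibbs_sample(
        rng, sites, couplings, cfg.n_sequences, cfg.burn_in + cfg.sweeps
    )
    codon_states = np.column_stack(
        [sites[i].global_states[local[i]] for i in range(cfg.n_columns)]
    )
    ids = [f"seq{s:05d}" for s in range(cfg.n_sequences)]
    codon_msa = Msa(codon_states, ids, CODON_ALPHABET)
    protein_msa = translate_msa(codon_msa)

    consensus = "".join(
        AA_ALPHABET.symbols[np.bincount(protein_msa.states[:, i]).argmax()]
        for i in range(cfg.n_columns)
    )
    chain = StructureChain(
        id=chain.id,
        sequence=consensus,
        cb_coords=chain.cb_coords,
        heavy_coords=chain.heavy_coords,
        resolution=chain.resolution,
    )
    return PlantedFamily(
        codon_msa=codon_msa,
        protein_msa=protein_msa,
        true_contacts=frozenset(contacts),
        aa_coupled=frozenset(contacts),
        codon_confound=frozenset(confounds),
        chain=chain,
        seed=cfg.seed,
        config=cfg,
    )


def confound_dissociation_check(family: PlantedFamily) -> dict:
    """Verify that confound pairs show the intended level dissociation.

    Every confound pair must have codon-level mutual information above
    the 95th percentile of non-planted pairs.  In ``codon_only`` mode
    the amino-acid-level MI must additionally fall below the non-planted
    median (the translated columns carry no signal); in ``aa_and_codon``
    mode the codon-minus-amino-acid MI excess must exceed the 95th
    percentile of the non-planted excess (the codon level carries signal
    beyond what translation explains).
    """
    from .frequencies import site_frequencies
    from .scores import mi_scores

    cfg = family.config
    if cfg is not None and cfg.beta_syn == 0:
        return {"applicable": False, "passed": None, "failures": [],
                "note": "beta_syn = 0: no confound couplings planted"}
    if not family.codon_confound:
        return {"applicable": False, "passed": None, "failures": [],
                "note": "no confound pairs planted"}

    sep = cfg.min_separation if cfg is not None else 5
    mi_aa = mi_scores(site_frequencies(family.protein_msa), "aa", sep).scores
    mi_c = mi_scores(site_frequencies(family.codon_msa), "codon", sep).scores

    length = family.protein_msa.n_columns
    planted = family.true_contacts | family.codon_confound
    bg = [
        (i, j)
        for i in range(length)
        for j in range(i + sep, length)
        if (i, j) not in planted
    ]
    bg_c = np.array([mi_c[i, j] for i, j in bg])
    bg_aa = np.array([mi_aa[i, j] for i, j in bg])
    bg_excess = bg_c - bg_aa
    c95 = float(np.percentile(bg_c, 95))
    aa_median = float(np.median(bg_aa))
    excess95 = float(np.percentile(bg_excess, 95))

    failures = []
    for i, j in sorted(family.codon_confound):
        ok = mi_c[i, j] > c95
        if cfg is None or cfg.confound_mode == "codon_only":
            ok = ok and mi_aa[i, j] <= aa_median
        else:
            ok = ok and (mi_c[i, j] - mi_aa[i, j]) > excess95
        if not ok:
            failures.append(
                {
                    "pair": (i, j),
                    "mi_codon": float(mi_c[i, j]),
                    "mi_aa": float(mi_aa[i, j]),
                    "codon_p95": c95,
                    "aa_median": aa_median,
                    "excess_p95": excess95,
                }
            )
    return {"applicable": True, "passed": not failures, "failures": failures}


def make_synthetic_chain(
    true_contacts: set[tuple[int, int]],
    length: int,
    seed: int,
    sequence: str | None = None,
    contact_max: float = 6.0,
    noncontact_min: float = 9.0,
    min_separation: int = 5,
    max_retries: int = 40,
) -> StructureChain:
    """Embed a contact set as single-atom residues in 3-D.

    Contact pairs end up closer than ``contact_max`` and every other
    pair at sequence separation >= ``min_separation`` farther than
    ``noncontact_min``, so the chain's contact map at the classic 8 Å
    cut-off reproduces the planted set exactly under all three contact
    definitions (one atom per residue).  Raises after ``max_retries``
    failed embeddings — a sign the contact set is too dense.
    """
    contacts = {(min(i, j), max(i, j)) for i, j in true_contacts}
    for i, j in contacts:
        if not (0 <= i < j < length):
            raise ValueError(f"contact pair {(i, j)} out of range")
        if j - i < min_separation:
            raise ValueError(f"contact pair {(i, j)} violates the separation rule")
    rng = np.random.default_rng(seed)
    contact_arr = np.array(sorted(contacts), dtype=int).reshape(-1, 2)
    repulse = np.array(
        [
            (i, j)
            for i in range(length)
            for j in range(i + min_separation, length)
            if (i, j) not in contacts
        ],
        dtype=int,
    ).reshape(-1, 2)
    # pure inequality penalties with soft bounds strictly inside the hard
    # ones: any layout with contacts below `hi` and the rest above `lo`
    # has exactly zero loss, which gives the optimiser a large feasible
    # interior to land in
    # margins must stay small: e.g. a 5-cycle of contacts is realisable
    # with side < 6 and diagonals > 9 (regular pentagon, diagonal 1.618x
    # side) only with little room to spare
    hi = contact_max - 0.1
    lo = noncontact_min + 0.1

    def loss_grad(flat: np.ndarray):
        x = flat.reshape(length, 3)
        val = 0.0
        grad = np.zeros_like(x)
        if len(contact_arr):
            d = x[contact_arr[:, 0]] - x[contact_arr[:, 1]]
            dist = np.linalg.norm(d, axis=1) + 1e-9
            viol = np.maximum(0.0, dist - hi)
            val += (viol**2).sum()
            g = (2 * viol / dist)[:, None] * d
            np.add.at(grad, contact_arr[:, 0], g)
            np.add.at(grad, contact_arr[:, 1], -g)
        if len(repulse):
            d = x[repulse[:, 0]] - x[repulse[:, 1]]
            dist = np.linalg.norm(d, axis=1) + 1e-9
            viol = np.maximum(0.0, lo - dist)
            val += (viol**2).sum()
            g = (-2 * viol / dist)[:, None] * d
            np.add.at(grad, repulse[:, 0], g)
            np.add.at(grad, repulse[:, 1], -g)
        return val, grad.ravel()

    box = max(20.0, 3.2 * length ** (1 / 3) * noncontact_min / 2)
    coords = None
    for _ in range(max_retries):
        init = rng.uniform(-box / 2, box / 2, size=(length, 3))
        res = minimize(loss_grad, init.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 3000})
        x = res.x.reshape(length, 3)
        ok = True
        if len(contact_arr):
            d = np.linalg.norm(x[contact_arr[:, 0]] - x[contact_arr[:, 1]], axis=1)
            ok &= bool((d < contact_max).all())
        if len(repulse):
            d = np.linalg.norm(x[repulse[:, 0]] - x[repulse[:, 1]], axis=1)
            ok &= bool((d > noncontact_min).all())
        if ok:
            coords = x
            break
    if coords is None:
        raise RuntimeError(
            "could not embed the contact set after "
            f"{max_retries} attempts; try a sparser contact set"
        )
    if sequence is None:
        letters = np.array(list("ACDEFHIKLMNPQRSTVWY"))  # glycine avoided
        sequence = "".join(rng.choice(letters, size=length))
    elif len(sequence) != length:
        raise ValueError("sequence length must equal chain length")
    return StructureChain(
        id=f"synthetic-{seed}",
        sequence=sequence,
        cb_coords=coords,
        heavy_coords=[coords[i : i + 1] for i in range(length)],
        resolution=1.0,
    )


def export_family(family: PlantedFamily, outdir) -> None:
    """Write a family to disk: alignments, truth tables, synthetic chain.

    Produces ``protein.fasta`` and ``codon.fasta`` (aligned), tab-separated
    truth tables with 1-based positions (``contacts.tsv``,
    ``confounds.tsv``), and ``chain.pdb``.
    """
    import os

    from .msa import write_msa
    from .structure import write_chain_pdb

    os.makedirs(outdir, exist_ok=True)
    write_msa(family.protein_msa, os.path.join(outdir, "protein.fasta"))
    write_msa(family.codon_msa, os.path.join(outdir, "codon.fasta"))
    for name, pairs in (
        ("contacts.tsv", family.true_contacts),
        ("confounds.tsv", family.codon_confound),
    ):
        with open(os.path.join(outdir, name), "w") as fh:
            for i, j in sorted(pairs):
                fh.write(f"{i + 1}\t{j + 1}\n")
    write_chain_pdb(family.chain, os.path.join(outdir, "chain.pdb"))
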