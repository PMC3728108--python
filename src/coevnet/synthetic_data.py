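"""Synthetic trees, alignments with planted covarying pairs, CDS and toy structures.

This module is the test substrate for the whole pipeline and the engine of the
coevolution null model: neutral alignments are sites evolving independently
down a tree under an exchangeable substitution process with configurable
stationary frequencies.  Planted pairs add covariation with a tunable coupling
probability rho — at rho=1 two columns are perfectly covarying through a fixed
state bijection, at rho=0 they are independent.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .io_formats import (
    GAP,
    ONE_TO_THREE,
    Alignment,
    Atom,
    Phylogeny,
    Residue,
    StructureModel,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# standard codon table restricted to the 20 amino acids, sense codons only
_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


@dataclass(frozen=True)
class PlantedPair:
    """A pair of columns forced to covary with coupling probability rho."""

    site_i: int  # 1-based column
    site_j: int
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0,1], got {self.rho}")
        if self.site_i == self.site_j:
            raise ValueError("planted sites must be distinct")


@dataclass(frozen=True)
class SimulationConfig:
    """Default generation profile for the study conditions emulated in tests.

    The depth default places mean pairwise amino-acid divergence of a neutral
    alignment inside the 0.30-0.40 band typical of deep bacterial protein
    families, the regime in which the covariation statistic is well behaved.
    """

    n_taxa: int = 30
    depth: float = 0.3
    length: int = 200
    frequencies: tuple[float, ...] | None = None  # None -> uniform over 20
    planted: tuple[PlantedPair, ...] = ()
    seed: int = 0


def _resolve_frequencies(frequencies) -> np.ndarray:
    if frequencies is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.shape != (len(AMINO_ACIDS),) or np.any(freqs < 0):
        raise ValueError("frequencies must be 20 non-negative numbers")
    total = freqs.sum()
    if total <= 0:
        raise ValueError("frequencies sum to zero")
    return freqs / total


def simulate_tree(n_taxa: int, depth: float, seed: int) -> Phylogeny:
    """Pure-birth tree with ``n_taxa`` leaves, scaled to mean root-to-tip ``depth``."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = _random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    mean_depth = float(np.mean(depths))
    scale = depth / mean_depth if mean_depth > 0 else 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{k}"
    return Phylogeny(tree)


def _state_bijection(rng: np.random.Generator, pairing: str) -> np.ndarray:
    """Fixed bijection pairing states across the two sites of a planted pair.

    ``identity`` (default) mirrors the exact state, so rho=1 makes the two
    columns literal copies with identical transition-score vectors;
    ``permutation`` uses a seeded random relabeling instead.
    """
    if pairing == "identity":
        return np.arange(len(AMINO_ACIDS))
    if pairing == "permutation":
        return rng.permutation(len(AMINO_ACIDS))
    raise ValueError(f"unknown state pairing {pairing!r}")


def evolve_alignment(
    tree: Phylogeny,
    length: int,
    frequencies=None,
    planted: tuple[PlantedPair, ...] | list[PlantedPair] = (),
    seed: int = 0,
    pairing: str = "identity",
) -> tuple[Alignment, list[PlantedPair]]:
    """Evolve an ungapped protein alignment site-independently down ``tree``.

    Substitution events arrive as a Poisson process at rate 1 per unit branch
    length per site; each event replaces the state by a draw from the
    stationary frequencies.  For a planted pair, every event at one site is
    mirrored at the partner site with probability rho, forcing the partner
    into the state paired with the new state under a fixed bijection (and
    symmetrically), so rho=1 keeps the two columns perfectly covarying.

    Returns the alignment and the planted-pair manifest.
    """
    freqs = _resolve_frequencies(frequencies)
    planted = tuple(planted)
    for p in planted:
        for s in (p.site_i, p.site_j):
            if not 1 <= s <= length:
                raise ValueError(f"planted site {s} outside 1..{length}")
    sites_in_pairs = [s for p in planted for s in (p.site_i, p.site_j)]
    if len(set(sites_in_pairs)) != len(sites_in_pairs):
        raise ValueError("planted pairs must not share sites")

    rng = np.random.default_rng(int(seed))
    n_states = len(AMINO_ACIDS)
    dtree = tree.dendropy_tree
    root = dtree.seed_node

    bijections = {p: _state_bijection(rng, pairing) for p in planted}
    inverse = {p: np.argsort(b) for p, b in bijections.items()}
    planted_cols = {}
    for p in planted:
        planted_cols[p.site_i - 1] = ("i", p)
        planted_cols[p.site_j - 1] = ("j", p)

    # root states
    root_states = rng.choice(n_states, size=length, p=freqs)
    for p in planted:
        if rng.random() < p.rho:
            root_states[p.site_j - 1] = bijections[p][root_states[p.site_i - 1]]

    # free sites: only the last event matters -> one stationary draw
    free = np.array(
        [k for k in range(length) if k not in planted_cols], dtype=int
    )
    states: dict[int, np.ndarray] = {id(root): root_states}
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        parent_states = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        s = parent_states.copy()
        n_events = rng.poisson(t, size=length)
        hit = free[n_events[free] > 0]
        if hit.size:
            s[hit] = rng.choice(n_states, size=hit.size, p=freqs)
        # planted sites: replay events in merged random order with mirroring
        for p in planted:
            ci, cj = p.site_i - 1, p.site_j - 1
            ki, kj = int(n_events[ci]), int(n_events[cj])
            if ki + kj == 0:
                continue
            order = rng.permutation(np.array([0] * ki + [1] * kj))
            for which in order:
                new = int(rng.choice(n_states, p=freqs))
                if which == 0:
                    s[ci] = new
                    if rng.random() < p.rho:
                        s[cj] = bijections[p][new]
                else:
                    s[cj] = new
                    if rng.random() < p.rho:
                        s[ci] = inverse[p][new]
        states[id(node)] = s

    ids, rows = [], []
    for leaf in dtree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        rows.append("".join(AMINO_ACIDS[k] for k in states[id(leaf)]))
    aln = Alignment(ids=tuple(ids), rows=tuple(rows), alphabet="protein")
    return aln, list(planted)


def evolve_protein_pair(
    tree: Phylogeny,
    length_a: int,
    length_b: int,
    frequencies=None,
    planted_a=(),
    planted_b=(),
    cross_planted: tuple[PlantedPair, ...] | list[PlantedPair] = (),
    seed: int = 0,
) -> tuple[Alignment, Alignment, dict]:
    """Two organism-paired alignments on one tree with optional cross-protein pairs.

    ``cross_planted`` pairs are (site in A, site in B, rho); intra-protein
    planted pairs use each protein's own coordinates.
    """
    shifted = [
        PlantedPair(p.site_i, p.site_j + length_a, p.rho) for p in cross_planted
    ]
    shifted += [PlantedPair(p.site_i, p.site_j, p.rho) for p in planted_a]
    shifted += [
        PlantedPair(p.site_i + length_a, p.site_j + length_a, p.rho)
        for p in planted_b
    ]
    combined, _ = evolve_alignment(
        tree, length_a + length_b, frequencies, shifted, seed
    )
    aln_a = Alignment(
        ids=combined.ids,
        rows=tuple(r[:length_a] for r in combined.rows),
        alphabet="protein",
    )
    aln_b = Alignment(
        ids=combined.ids,
        rows=tuple(r[length_a:] for r in combined.rows),
        alphabet="protein",
    )
    manifest = {
        "intra_a": list(planted_a),
        "intra_b": list(planted_b),
        "cross": list(cross_planted),
    }
    return aln_a, aln_b, manifest


def emit_cds(
    aln: Alignment, seed: int = 0, synonymous_divergence: float = 0.3
) -> Alignment:
    """Reverse-translate a protein alignment into an in-frame CDS alignment.

    Each column gets a reference codon per amino acid; each sequence keeps the
    reference codon or, with probability ``synonymous_divergence``, switches to
    a random synonymous alternative.  Gaps become codon gaps.
    """
    if aln.alphabet != "protein":
        raise ValueError("emit_cds needs a protein alignment")
    table = _codon_table()
    rng = np.random.default_rng(int(seed))
    out_rows: list[list[str]] = [[] for _ in aln.ids]
    for col in range(aln.length):
        ref: dict[str, str] = {}
        for r, row in enumerate(aln.rows):
            aa = row[col]
            if aa == GAP:
                out_rows[r].append("-" * 3)
                continue
            if aa not in table:
                raise ValueError(f"non-standard residue {aa!r} at column {col + 1}")
            if aa not in ref:
                ref[aa] = table[aa][int(rng.integers(len(table[aa])))]
            codon = ref[aa]
            alts = [c for c in table[aa] if c != codon]
            if alts and rng.random() < synonymous_divergence:
                codon = alts[int(rng.integers(len(alts)))]
            out_rows[r].append(codon)
    return Alignment(
        ids=aln.ids, rows=tuple("".join(r) for r in out_rows), alphabet="dna"
    )


def _uniform_ball(rng: np.random.Generator, n: int, radius: float, center) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return np.asarray(center) + v * r[:, None]


def synthetic_structure(
    n_residues: int,
    groups: dict[str, list[int]] | None = None,
    cluster_radius: float = 4.0,
    spread: float = 40.0,
    helix_ranges: list[tuple[int, int]] | None = None,
    sheet_ranges: list[tuple[int, int]] | None = None,
    seed: int = 0,
    chain_id: str = "A",
) -> tuple[StructureModel, str]:
    """A toy single-chain structure with designated spatially compact groups.

    Background residues are uniform in a ball whose mean pairwise distance is
    ``spread``; each group's residues sit in a tight ball so that all pairwise
    carbon-carbon distances are below ``cluster_radius``.  Returns the model
    and its PDB text (ATOM + HELIX/SHEET records).
    """
    groups = groups or {}
    if cluster_radius <= 1.5:
        raise ValueError("infeasible packing: cluster_radius too small")
    if cluster_radius >= spread:
        raise ValueError("cluster_radius must be below background spread")
    all_members = [m for g in groups.values() for m in g]
    if len(set(all_members)) != len(all_members):
        raise ValueError("groups must be disjoint")
    for m in all_members:
        if not 1 <= m <= n_residues:
            raise ValueError(f"group residue {m} outside 1..{n_residues}")

    rng = np.random.default_rng(int(seed))
    # mean pairwise distance of uniform points in a ball of radius R is 36R/35
    background_radius = spread * 35.0 / 36.0
    coords = _uniform_ball(rng, n_residues, background_radius, (0.0, 0.0, 0.0))
    # side-chain offset of 0.5 A means point spread must leave 1.0 A of slack
    tight = (cluster_radius - 1.0) * 0.45
    for members in groups.values():
        center = _uniform_ball(rng, 1, background_radius * 0.5, (0, 0, 0))[0]
        pts = _uniform_ball(rng, len(members), tight, center)
        for m, pt in zip(members, pts):
            coords[m - 1] = pt

    helix_ranges = helix_ranges or []
    sheet_ranges = sheet_ranges or []

    def ss_of(number: int) -> str:
        if any(a <= number <= b for a, b in helix_ranges):
            return "helix"
        if any(a <= number <= b for a, b in sheet_ranges):
            return "strand"
        return "coil"

    residues = []
    seq = rng.choice(list(ONE_TO_THREE.values()), size=n_residues)
    for k in range(n_residues):
        x, y, z = coords[k]
        offset = rng.normal(size=3)
        offset *= 0.5 / np.linalg.norm(offset)
        atoms = (
            Atom("CA", x, y, z),
            Atom("CB", x + offset[0], y + offset[1], z + offset[2]),
        )
        residues.append(
            Residue(number=k + 1, name=str(seq[k]), atoms=atoms, ss_class=ss_of(k + 1))
        )
    model = StructureModel(chain_id=chain_id, residues=tuple(residues))
    return model, structure_to_pdb(model, helix_ranges, sheet_ranges)


def structure_to_pdb(
    model: StructureModel,
    helix_ranges: list[tuple[int, int]] | None = None,
    sheet_ranges: list[tuple[int, int]] | None = None,
) -> str:
    """Serialize a StructureModel as minimal fixed-column PDB text."""
    lines = []
    ch = model.chain_id
    for k, (a, b) in enumerate(helix_ranges or [], start=1):
        lines.append(
            f"HELIX  {k:3d} {k:3d} ALA {ch} {a:4d}  ALA {ch} {b:4d}  1"
            f"{'':30s}{b - a + 1:5d}"
        )
    for k, (a, b) in enumerate(sheet_ranges or [], start=1):
        lines.append(
            f"SHEET  {k:3d} S{k:<2d} 1 ALA {ch}{a:4d}  ALA {ch}{b:4d}  0"
        )
    serial = 1
    for res in model.residues:
        for atom in res.atoms:
            name = atom.name.strip()
            # PDB alignment rule: 1-3 char names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {padded}{'':1s}{res.name:>3s} {ch}"
                f"{res.number:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
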