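"""Alignment curation and alignment-to-structure coordinate mapping.

Covers the curation steps applied before coevolution detection: removing
redundant sequences, collapsing within-species gene duplicates, pairing two
alignments by organism for inter-protein analysis, p-distance summaries,
neighbor-joining tree estimation, and the gap-aware map from alignment columns
to structure residue numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import GAP, Alignment, Phylogeny, StructureModel


def deduplicate(aln: Alignment) -> Alignment:
    """Drop sequences whose residue rows are identical, keeping the first."""
    seen: set[str] = set()
    keep: list[int] = []
    for k, row in enumerate(aln.rows):
        if row not in seen:
            seen.add(row)
            keep.append(k)
    if len(keep) == len(aln.ids):
        return aln
    return Alignment(
        ids=tuple(aln.ids[k] for k in keep),
        rows=tuple(aln.rows[k] for k in keep),
        alphabet=aln.alphabet,
    )


def drop_within_species_duplicates(
    aln: Alignment, species_of_id: Mapping[str, str]
) -> Alignment:
    """Keep at most one sequence per species (first occurrence)."""
    missing = [i for i in aln.ids if i not in species_of_id]
    if missing:
        raise KeyError(f"ids missing from species mapping: {missing}")
    seen: set[str] = set()
    keep: list[int] = []
    for k, seq_id in enumerate(aln.ids):
        sp = species_of_id[seq_id]
        if sp not in seen:
            seen.add(sp)
            keep.append(k)
    if len(keep) == len(aln.ids):
        return aln
    return Alignment(
        ids=tuple(aln.ids[k] for k in keep),
        rows=tuple(aln.rows[k] for k in keep),
        alphabet=aln.alphabet,
    )


def pair_by_organism(
    aln_a: Alignment,
    aln_b: Alignment,
    organism_of_id: Mapping[str, str],
    relabel: bool = False,
) -> tuple[Alignment, Alignment]:
    """Restrict both alignments to organisms present in each, same row order.

    Within each alignment an organism must resolve to a single sequence (run
    :func:`drop_within_species_duplicates` first if it does not).  With
    ``relabel=True`` the returned rows carry organism labels as ids, so both
    alignments share identical ids — the form inter-protein detection expects.
    """
    def by_organism(aln: Alignment) -> dict[str, str]:
        out: dict[str, str] = {}
        for i in aln.ids:
            if i not in organism_of_id:
                raise KeyError(f"id {i!r} missing from organism mapping")
            org = organism_of_id[i]
            if org in out:
                raise ValueError(f"organism {org!r} has multiple sequences")
            out[org] = i
        return out

    orgs_a = by_organism(aln_a)
    orgs_b = by_organism(aln_b)
    shared = [o for o in orgs_a if o in orgs_b]  # order of aln_a
    if not shared:
        raise ValueError("no organisms shared between the two alignments")
    out_a = aln_a.subset([orgs_a[o] for o in shared])
    out_b = aln_b.subset([orgs_b[o] for o in shared])
    if relabel:
        out_a = Alignment(tuple(shared), out_a.rows, out_a.alphabet)
        out_b = Alignment(tuple(shared), out_b.rows, out_b.alphabet)
    return out_a, out_b


def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of gapped columns."""
    chars = aln.to_char_array()
    n = aln.n_sequences
    gap = chars == GAP
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            both = ~(gap[a] | gap[b])
            overlap = int(both.sum())
            if overlap == 0:
                raise ValueError(
                    f"sequences {aln.ids[a]!r} and {aln.ids[b]!r} share no "
                    "ungapped columns"
                )
            mism = int((chars[a][both] != chars[b][both]).sum())
            out[a, b] = out[b, a] = mism / overlap
    return out


def mean_divergence(aln: Alignment) -> float:
    """Mean p-distance over all unordered sequence pairs, in [0, 1]."""
    d = p_distance_matrix(aln)
    n = aln.n_sequences
    return float(d[np.triu_indices(n, k=1)].mean())


def _distance_matrix_to_dendropy(
    ids: Sequence[str], d: np.ndarray
) -> dendropy.PhylogeneticDistanceMatrix:
    import io as _io

    buf = _io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for a, name in enumerate(ids):
        buf.write(name + "," + ",".join(f"{d[a, b]:.12g}" for b in range(len(ids))) + "\n")
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")


def nj_tree(aln: Alignment) -> Phylogeny:
    """Neighbor-joining tree from the p-distance matrix.

    Negative branch lengths (an NJ artifact) are clamped to zero.
    """
    if aln.n_sequences < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    d = p_distance_matrix(aln)
    pdm = _distance_matrix_to_dendropy(list(aln.ids), d)
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return Phylogeny(tree)


@dataclass(frozen=True)
class SiteMap:
    """Map from 1-based alignment columns to structure residue numbers."""

    column_to_residue: dict[int, int]
    unmapped_columns: tuple[int, ...]
    mismatches: tuple[int, ...] = ()  # columns where residues disagreed

    def residue(self, column: int) -> int | None:
        return self.column_to_residue.get(column)

    @property
    def residue_to_column(self) -> dict[int, int]:
        return {v: k for k, v in self.column_to_residue.items()}


def column_to_residue_map(
    aln: Alignment, ref_id: str, structure: StructureModel
) -> SiteMap:
    """Gap-skip map: k-th ungapped column of the reference row -> k-th residue.

    The ungapped reference row must have exactly as many residues as the
    structure chain; columns whose amino acid differs from the structure's are
    mapped but reported in ``mismatches``.
    """
    row = aln.row(ref_id)
    ungapped_cols = [k + 1 for k, c in enumerate(row) if c != GAP]
    residues = structure.residues
    if len(ungapped_cols) != len(residues):
        raise ValueError(
            f"ungapped reference has {len(ungapped_cols)} residues but the "
            f"structure chain has {len(residues)}"
        )
    struct_seq = structure.sequence
    mapping: dict[int, int] = {}
    mismatches: list[int] = []
    for k, col in enumerate(ungapped_cols):
        mapping[col] = residues[k].number
        if row[col - 1] != struct_seq[k]:
            mismatches.append(col)
    unmapped = tuple(
        c for c in range(1, aln.length + 1) if c not in mapping
    )
    return SiteMap(
        column_to_residue=mapping,
        unmapped_columns=unmapped,
        mismatches=tuple(mismatches),
    )
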