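"""Readers, writers and in-memory containers for the pipeline's standard formats.

Alignments are gapped FASTA, trees are Newick, structures are PDB-format text
(ATOM plus HELIX/SHEET records), and results go out as sorted TSV tables with a
JSON provenance block.  Columns and residues are addressed 1-based throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

GAP = "-"

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment with unique identifiers.

    Invariants: all rows equal length, ids unique, at least two sequences,
    gap character ``-``.  Columns are addressed 1-based.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in length")
        if len(self.ids) < 2:
            raise FormatError("alignment needs at least 2 sequences")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise FormatError(f"duplicate sequence id: {i!r}")
                seen.add(i)
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.alphabet not in ("protein", "dna"):
            raise FormatError(f"unknown alphabet {self.alphabet!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"id {seq_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        return "".join(r[col - 1] for r in self.rows)

    def to_char_array(self) -> np.ndarray:
        """(n_sequences, length) array of single characters."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_sequences, self.length).astype("U1")

    def subset(self, keep_ids: Sequence[str]) -> "Alignment":
        """Restrict to ``keep_ids`` in the given order."""
        index = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in keep_ids if i not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return replace(
            self,
            ids=tuple(keep_ids),
            rows=tuple(self.rows[index[i]] for i in keep_ids),
        )

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


def read_alignment(path: str | Path, alphabet: str = "protein") -> Alignment:
    """Read a gapped FASTA alignment.

    The id is the first whitespace token of the header; the rest is ignored.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(ids=tuple(ids), rows=tuple(rows), alphabet=alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in zip(aln.ids, aln.rows):
            fh.write(f">{i}\n{r}\n")


# ---------------------------------------------------------------------------
# Phylogeny


class Phylogeny:
    """A phylogenetic tree with non-negative branch lengths over leaf labels.

    Thin wrapper over a :class:`dendropy.Tree`; exposes exactly what the
    pipeline needs (patristic distances, pruning, Newick round trip).
    """

    def __init__(self, tree: dendropy.Tree):
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")
        self._tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"unparsable Newick: {exc}") from exc
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    def __len__(self) -> int:
        return len(self.leaf_labels)

    def patristic_matrix(self, ids: Sequence[str]) -> np.ndarray:
        """Symmetric matrix of path-length distances for ``ids``."""
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        missing = [i for i in ids if i not in taxa]
        if missing:
            raise KeyError(f"ids not on tree: {missing}")
        n = len(ids)
        out = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                d = pdm.patristic_distance(taxa[ids[a]], taxa[ids[b]])
                out[a, b] = out[b, a] = d
        return out

    def prune_to(self, ids: Sequence[str]) -> "Phylogeny":
        """Subtree induced by ``ids``; path lengths between kept leaves preserved."""
        sub = self._tree.extract_tree_with_taxa_labels(labels=list(ids))
        return Phylogeny(sub)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()


def read_tree(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path).read_text())


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Structure


@dataclass(frozen=True)
class Atom:
    name: str
    x: float
    y: float
    z: float

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_carbon(self) -> bool:
        # in standard amino acids every atom name starting with C is a carbon
        n = self.name.strip()
        return n.startswith("C") and n not in ("CL",)


@dataclass(frozen=True)
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: tuple[Atom, ...]
    ss_class: str = "coil"  # helix | strand | coil

    def carbon_coords(self, ca_only: bool = False) -> np.ndarray:
        if ca_only:
            sel = [a for a in self.atoms if a.name.strip() == "CA"]
        else:
            sel = [a for a in self.atoms if a.is_carbon]
        if not sel:
            raise ValueError(f"residue {self.number} has no carbon atoms")
        return np.array([[a.x, a.y, a.z] for a in sel])


@dataclass(frozen=True)
class StructureModel:
    """One chain of a protein structure: numbered residues with coordinates."""

    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"chain {self.chain_id!r} has no residues")
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise FormatError("residue numbers not strictly increasing")
        for r in self.residues:
            if not r.atoms:
                raise FormatError(f"residue {r.number} has no atoms")

    @property
    def residue_numbers(self) -> tuple[int, ...]:
        return tuple(r.number for r in self.residues)

    @property
    def residue_map(self) -> dict[int, Residue]:
        return {r.number: r for r in self.residues}

    @property
    def sequence(self) -> str:
        """One-letter sequence (X for non-standard residues)."""
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def _secondary_structure_ranges(path: Path) -> dict[str, list[tuple[str, int, int]]]:
    """Scan HELIX/SHEET records (fixed columns per the PDB format)."""
    out: dict[str, list[tuple[str, int, int]]] = {"helix": [], "strand": []}
    with open(path) as fh:
        for line in fh:
            try:
                if line.startswith("HELIX"):
                    out["helix"].append(
                        (line[19].strip(), int(line[21:25]), int(line[33:37]))
                    )
                elif line.startswith("SHEET"):
                    out["strand"].append(
                        (line[21].strip(), int(line[22:26]), int(line[33:37]))
                    )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed record: {line.rstrip()}") from exc
    return out


def read_structure(path: str | Path, chain: str) -> StructureModel:
    """Read one chain from PDB-format text.

    Only ATOM records of the requested chain are used; secondary structure is
    taken from HELIX/SHEET records (coil elsewhere).
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure("s", str(path))[0]
    if chain not in [c.id for c in model]:
        raise FormatError(
            f"chain {chain!r} absent; present: {[c.id for c in model]}"
        )
    ss = _secondary_structure_ranges(path)

    def ss_class(number: int) -> str:
        for cls in ("helix", "strand"):
            for ch, start, end in ss[cls]:
                if ch == chain and start <= number <= end:
                    return cls
        return "coil"

    residues = []
    for res in model[chain]:
        if res.id[0] != " ":  # skip HETATM / waters
            continue
        atoms = tuple(
            Atom(a.get_name(), *map(float, a.get_coord())) for a in res
        )
        residues.append(
            Residue(
                number=res.id[1],
                name=res.get_resname(),
                atoms=atoms,
                ss_class=ss_class(res.id[1]),
            )
        )
    if not residues:
        raise FormatError(f"no ATOM records for chain {chain!r}")
    return StructureModel(chain_id=chain, residues=tuple(residues))


# ---------------------------------------------------------------------------
# Result bundle


@dataclass
class ResultBundle:
    """All tabular outputs of a run plus the provenance that produced them."""

    pair_table: pd.DataFrame | None = None
    support_table: pd.DataFrame | None = None
    edge_table: pd.DataFrame | None = None
    centrality_table: pd.DataFrame | None = None
    sector_table: pd.DataFrame | None = None
    structure_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    _FILES = {
        "pair_table": "pairs.tsv",
        "support_table": "support.tsv",
        "edge_table": "edges.tsv",
        "centrality_table": "centrality.tsv",
        "sector_table": "sectors.tsv",
        "structure_table": "structure.tsv",
    }


def write_results(bundle: ResultBundle, out_dir: str | Path) -> list[Path]:
    """Write every present table as TSV plus ``provenance.json``.

    Rows are sorted by all columns so reruns with identical inputs are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for attr, fname in ResultBundle._FILES.items():
        table = getattr(bundle, attr)
        if table is None:
            continue
        table = table.copy()
        if len(table):
            table = table.sort_values(list(table.columns), kind="mergesort")
        dest = out_dir / fname
        table.to_csv(dest, sep="\t", index=False, float_format="%.10g")
        written.append(dest)
    prov = out_dir / "provenance.json"
    prov.write_text(
        json.dumps(bundle.provenance, indent=2, sort_keys=True, default=str)
        + "\n"
    )
    written.append(prov)
    return written


# ---------------------------------------------------------------------------
# Tabular helpers (clade maps, domain annotations)


def read_id_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV mapping table (columns like id, organism, species, clade)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "id" not in table.columns:
        raise FormatError(f"{path}: mapping table needs an 'id' column")
    if table["id"].duplicated().any():
        dup = table["id"][table["id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate id {dup!r}")
    return table


def mapping_from_table(table: pd.DataFrame, value_column: str) -> dict[str, str]:
    if value_column not in table.columns:
        raise FormatError(f"mapping table lacks column {value_column!r}")
    return dict(zip(table["id"], table[value_column]))
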