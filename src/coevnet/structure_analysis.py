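"""Structural statistics for coevolving site groups.

Distance between two residues is the minimum over all carbon-carbon atom
pairs ("proximal carbons"; a Calpha-only mode exists for sensitivity checks).
Group compactness is the mean of those minimum distances over all unordered
residue pairs; its significance comes from random equal-size residue sets.
Secondary-structure enrichment is a plain chi-square of observed versus
composition-expected counts over {helix, strand, coil}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .io_formats import StructureModel

PROXIMAL_CUTOFF = 4.0  # Angstrom; "proximal" means strictly below

SS_CLASSES = ("helix", "strand", "coil")


def min_carbon_distance(
    structure: StructureModel, res_a: int, res_b: int, ca_only: bool = False
) -> float:
    """Minimum Euclidean distance between carbon atoms of two residues (A)."""
    rmap = structure.residue_map
    for r in (res_a, res_b):
        if r not in rmap:
            raise KeyError(f"residue {r} not in chain {structure.chain_id}")
    ca = rmap[res_a].carbon_coords(ca_only=ca_only)
    cb = rmap[res_b].carbon_coords(ca_only=ca_only)
    return float(cdist(ca, cb).min())


def is_proximal(
    structure: StructureModel, res_a: int, res_b: int, cutoff: float = PROXIMAL_CUTOFF
) -> bool:
    """Strictly-below-cutoff contact test (4 A exactly is not proximal)."""
    return min_carbon_distance(structure, res_a, res_b) < cutoff


def distance_table(
    structure: StructureModel, residues: Sequence[int], ca_only: bool = False
) -> pd.DataFrame:
    rows = []
    residues = sorted(set(residues))
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            d = min_carbon_distance(
                structure, residues[a], residues[b], ca_only=ca_only
            )
            rows.append(
                {
                    "residue_a": residues[a],
                    "residue_b": residues[b],
                    "distance": d,
                    "proximal": d < PROXIMAL_CUTOFF,
                }
            )
    return pd.DataFrame(
        rows, columns=["residue_a", "residue_b", "distance", "proximal"]
    )


def group_compactness(
    structure: StructureModel, residues: Sequence[int], ca_only: bool = False
) -> float:
    """Mean pairwise minimum-carbon distance over the group (A)."""
    residues = sorted(set(residues))
    if len(residues) < 2:
        raise ValueError("compactness needs at least 2 residues")
    total = 0.0
    n = 0
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            total += min_carbon_distance(
                structure, residues[a], residues[b], ca_only=ca_only
            )
            n += 1
    return total / n


def cluster_significance(
    structure: StructureModel,
    residues: Sequence[int],
    candidate_pool: Sequence[int],
    n_random: int = 1000,
    seed: int = 0,
    ca_only: bool = False,
) -> float:
    """Add-one p-value: how often random equal-size sets are as compact.

    p = (1 + #{random sets with compactness <= observed}) / (n_random + 1).
    """
    residues = sorted(set(residues))
    pool = sorted(set(candidate_pool))
    if not set(residues) <= set(pool):
        raise ValueError("candidate pool must contain the group")
    if len(pool) < len(residues):
        raise ValueError("pool smaller than the group")
    if n_random < 100:
        raise ValueError("n_random must be at least 100")
    observed = group_compactness(structure, residues, ca_only=ca_only)
    rng = np.random.default_rng(int(seed))
    pool_arr = np.array(pool)
    k = len(residues)
    hits = 0
    for _ in range(n_random):
        pick = pool_arr[rng.choice(len(pool_arr), size=k, replace=False)]
        if group_compactness(structure, pick.tolist(), ca_only=ca_only) <= observed:
            hits += 1
    return (hits + 1) / (n_random + 1)


@dataclass(frozen=True)
class EnrichmentTable:
    """Secondary-structure enrichment of a site group (chi-square)."""

    observed: dict[str, int]
    expected: dict[str, float]
    class_totals: dict[str, int]
    chi2: float
    df: int
    p: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ss_class": c,
                "observed": self.observed[c],
                "expected": self.expected[c],
                "class_total": self.class_totals[c],
            }
            for c in SS_CLASSES
        ]
        return pd.DataFrame(rows)


def ss_enrichment(
    structure: StructureModel, residues: Sequence[int]
) -> EnrichmentTable:
    """Observed vs composition-expected counts of group sites per SS class.

    Expected_k = n * (class residue total / chain total).  Classes with zero
    expected count are dropped from the statistic with df reduced; a chain
    with a single represented class has no degrees of freedom and errors.
    """
    residues = sorted(set(residues))
    if not residues:
        raise ValueError("empty residue group")
    rmap = structure.residue_map
    missing = [r for r in residues if r not in rmap]
    if missing:
        raise KeyError(f"residues not in chain: {missing}")
    totals = {c: 0 for c in SS_CLASSES}
    for res in structure.residues:
        totals[res.ss_class] += 1
    n = len(residues)
    n_chain = len(structure.residues)
    observed = {c: 0 for c in SS_CLASSES}
    for r in residues:
        observed[rmap[r].ss_class] += 1
    expected = {c: n * totals[c] / n_chain for c in SS_CLASSES}
    tested = [c for c in SS_CLASSES if expected[c] > 0]
    df = len(tested) - 1
    if df == 0:
        raise ValueError("single secondary-structure class: no test possible")
    chi2 = sum((observed[c] - expected[c]) ** 2 / expected[c] for c in tested)
    p = float(stats.chi2.sf(chi2, df))
    return EnrichmentTable(
        observed=observed,
        expected=expected,
        class_totals=totals,
        chi2=float(chi2),
        df=df,
        p=p,
    )
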