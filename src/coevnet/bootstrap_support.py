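"""Phylogenetic pair bootstrap: support for detected coevolving site pairs.

Each replicate draws a random subsample of sequences (without replacement),
prunes the tree accordingly, rebuilds the null at reduced simulation effort,
and asks whether each originally detected column pair is detected again at the
same significance level.  A pair's support is the fraction of replicates in
which it reappears; pairs above the support threshold (strictly) are retained
as consistently coevolving.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coevolution_core import (
    DivergenceMatrix,
    NullModel,
    PairResult,
    build_null,
    row_pair_correlations,
    site_vector_matrix,
)
from .io_formats import Alignment, Phylogeny

DEFAULT_FRACTION = 0.8
DEFAULT_THRESHOLD = 0.70


@dataclass(frozen=True)
class SupportRecord:
    """Bootstrap support of one base pair of sites."""

    protein_a: str
    site_a: int
    protein_b: str
    site_b: int
    n_replicates: int
    n_detected: int
    support: float
    retained: bool

    @property
    def key(self):
        return (self.protein_a, self.site_a, self.protein_b, self.site_b)


def resample_sequences(
    aln: Alignment,
    tree: Phylogeny,
    fraction: float,
    seed: int | np.random.Generator,
) -> tuple[Alignment, Phylogeny]:
    """Uniform subsample of ceil(fraction * n) sequences, tree pruned to match.

    Sampling is without replacement; the retained rows keep their original
    order so replicates stay deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(int(seed))
    )
    n = aln.n_sequences
    k = math.ceil(fraction * n)
    if k < 4:
        raise ValueError(f"subsample of {k} sequences is too small")
    chosen = np.sort(rng.choice(n, size=k, replace=False))
    ids = [aln.ids[i] for i in chosen]
    return aln.subset(ids), tree.prune_to(ids)


def _base_pair_detected(
    aln: Alignment,
    aln_b: Alignment | None,
    times: DivergenceMatrix,
    base_pairs: Sequence[PairResult],
    alpha: float,
    null: NullModel,
    rng: np.random.Generator,
) -> list[bool]:
    """Re-detection flags for the base pairs on one replicate dataset.

    Detection of a specific pair only needs that pair's correlation and the
    null exceedance, so only the base columns are scored.
    """
    V_a, _ = site_vector_matrix(aln, times)
    V_b = V_a if aln_b is None else site_vector_matrix(aln_b, times)[0]
    ii = np.array([p.site_a - 1 for p in base_pairs], dtype=int)
    jj = np.array([p.site_b - 1 for p in base_pairs], dtype=int)
    if aln_b is None:
        r = row_pair_correlations(V_a, ii, jj)
    else:
        r = np.array(
            [
                row_pair_correlations(
                    np.vstack([V_a[i], V_b[j]]), np.array([0]), np.array([1])
                )[0]
                for i, j in zip(ii, jj)
            ]
        )
    p = null.exceedance_p(r, rng=rng)
    p = np.atleast_1d(p)
    return [bool(np.isfinite(rv) and pv < alpha) for rv, pv in zip(r, p)]


def bootstrap_pairs(
    aln: Alignment,
    tree: Phylogeny,
    base_pairs: Sequence[PairResult],
    times: DivergenceMatrix | None = None,
    n_reps: int = 1000,
    fraction: float = DEFAULT_FRACTION,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = 0.001,
    seed: int = 0,
    aln_b: Alignment | None = None,
    null_sim_alignments: int = 2,
    null_samples: int = 20_000,
) -> list[SupportRecord]:
    """Support for each base pair over ``n_reps`` phylogenetic subsamples.

    ``aln_b`` switches to inter-protein mode: both alignments are subsampled
    to the same rows and pair sites index protein A and protein B columns.
    Replicates where detection fails outright count as non-detections.  Each
    replicate derives its seed from ``seed`` + replicate index, so replicates
    are independent and order-insensitive.
    """
    if aln_b is not None and aln_b.ids != aln.ids:
        raise ValueError("inter-protein bootstrap needs organism-paired rows")
    if times is None:
        times = DivergenceMatrix(
            ids=aln.ids, matrix=tree.patristic_matrix(aln.ids), mode="patristic"
        )
    base_pairs = list(base_pairs)
    counts = np.zeros(len(base_pairs), dtype=int)
    for rep in range(n_reps):
        rep_seed = (int(seed) + rep) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        try:
            sub, sub_tree = resample_sequences(aln, tree, fraction, rng)
            sub_ids = list(sub.ids)
            # distances between retained sequences are unchanged by subsampling
            sub_times = times.subset(sub_ids)
            sub_b = aln_b.subset(sub_ids) if aln_b is not None else None
            null_aln = sub if sub_b is None else _concat(sub, sub_b)
            null = build_null(
                null_aln,
                sub_tree,
                sub_times,
                n_sim_alignments=null_sim_alignments,
                n_samples=null_samples,
                seed=int(rng.integers(2**31 - 1)),
                sim_length=max(null_aln.length, 10),
            )
            detected = _base_pair_detected(
                sub, sub_b, sub_times, base_pairs, alpha, null, rng
            )
            counts += np.asarray(detected, dtype=int)
        except (ValueError, KeyError):
            continue  # replicate counts as non-detection for every pair
    records = []
    for p, c in zip(base_pairs, counts):
        support = c / n_reps
        records.append(
            SupportRecord(
                protein_a=p.protein_a,
                site_a=p.site_a,
                protein_b=p.protein_b,
                site_b=p.site_b,
                n_replicates=n_reps,
                n_detected=int(c),
                support=support,
                retained=bool(support > threshold),
            )
        )
    return records


def _concat(a: Alignment, b: Alignment) -> Alignment:
    return Alignment(
        ids=a.ids,
        rows=tuple(ra + rb for ra, rb in zip(a.rows, b.rows)),
        alphabet="protein",
    )


def support_table(records: Sequence[SupportRecord]):
    import pandas as pd

    table = pd.DataFrame(
        [
            {
                "protein_a": r.protein_a,
                "site_a": r.site_a,
                "protein_b": r.protein_b,
                "site_b": r.site_b,
                "n_reps": r.n_replicates,
                "n_detected": r.n_detected,
                "support": r.support,
                "retained": r.retained,
            }
            for r in records
        ],
        columns=[
            "protein_a", "site_a", "protein_b", "site_b",
            "n_reps", "n_detected", "support", "retained",
        ],
    )
    return table.sort_values(
        ["protein_a", "site_a", "protein_b", "site_b"], kind="mergesort"
    ).reset_index(drop=True)
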