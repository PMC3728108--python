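"""Entropy-based sector statistics and the between-clade independence test.

Conservation of a site is measured as a two-outcome relative entropy: the
frequency f of the column's modal residue against the background frequency q
of that amino acid, D = f ln(f/q) + (1-f) ln((1-f)/(1-q)).  A site group's
entropy D_S uses the joint modal pattern (all sites modal simultaneously)
against the product background, and the correlation entropy
I_S = D_S - sum_i D_i captures covariation beyond per-site conservation.

Two site groups g1, g2 from the same protein domain are statistically
independent when theta = I_(g1 u g2) - (I_g1 + I_g2) is indistinguishable
from the theta of random same-size groups drawn from the domain's site pool
(z against the null replicates, two-sided normal test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GAP, Alignment


def binary_relative_entropy(f: float, q: float) -> float:
    """D = f ln(f/q) + (1-f) ln((1-f)/(1-q)), with 0 ln 0 = 0.

    Non-negative; zero exactly when f equals q.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"f={f} outside [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"background q={q} outside (0, 1)")
    out = 0.0
    if f > 0:
        out += f * math.log(f / q)
    if f < 1:
        out += (1.0 - f) * math.log((1.0 - f) / (1.0 - q))
    return out


@dataclass(frozen=True)
class Background:
    """Per-column modal residue and its alignment-wide background frequency."""

    modal: dict[int, str]  # 1-based column -> modal residue
    q: dict[int, float]  # column -> background frequency of that residue


def compute_background(aln: Alignment, columns: Sequence[int] | None = None) -> Background:
    """Modal residue per column; q = frequency of that amino acid across the
    whole alignment (all ungapped positions), clipped inside (0, 1)."""
    columns = list(columns) if columns is not None else list(range(1, aln.length + 1))
    global_counts: dict[str, int] = {}
    total = 0
    for row in aln.rows:
        for c in row:
            if c != GAP:
                global_counts[c] = global_counts.get(c, 0) + 1
                total += 1
    if total == 0:
        raise ValueError("alignment is entirely gapped")
    modal: dict[int, str] = {}
    q: dict[int, float] = {}
    eps = 1.0 / (total + 1)
    for col in columns:
        residues = [c for c in aln.column(col) if c != GAP]
        if not residues:
            raise ValueError(f"column {col} is fully gapped")
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        # deterministic tie-break: highest count, then alphabetical
        m = min(counts, key=lambda a: (-counts[a], a))
        modal[col] = m
        q[col] = min(max(global_counts.get(m, 0) / total, eps), 1.0 - eps)
    return Background(modal=modal, q=q)


def _modal_frequency(aln: Alignment, column: int, modal: str) -> float:
    residues = [c for c in aln.column(column) if c != GAP]
    if not residues:
        raise ValueError(f"column {column} is fully gapped")
    return residues.count(modal) / len(residues)


def site_entropy(
    aln: Alignment, column: int, q: float | None = None, background: Background | None = None
) -> float:
    """Conservation D_i of one column against its background frequency."""
    if background is None or column not in background.modal:
        background = compute_background(aln, [column])
    modal = background.modal[column]
    qv = q if q is not None else background.q[column]
    f = _modal_frequency(aln, column, modal)
    return binary_relative_entropy(f, qv)


def _joint_modal_frequency(
    aln: Alignment, sites: Sequence[int], background: Background
) -> float:
    """Fraction of rows (ungapped at every site of S) modal at all sites."""
    usable = 0
    hits = 0
    cols = [s - 1 for s in sites]
    modals = [background.modal[s] for s in sites]
    for row in aln.rows:
        chars = [row[c] for c in cols]
        if GAP in chars:
            continue
        usable += 1
        if all(c == m for c, m in zip(chars, modals)):
            hits += 1
    if usable == 0:
        raise ValueError(f"no sequence is ungapped at all of {list(sites)}")
    return hits / usable


def group_entropy(
    aln: Alignment, sites: Sequence[int], background: Background | None = None
) -> float:
    """Joint conservation D_S of a site group.

    f_S is the fraction of sequences carrying the modal residue at every site
    simultaneously; the background is the product of the per-site background
    frequencies (the independence expectation of the joint modal pattern).
    """
    sites = list(sites)
    if not sites:
        raise ValueError("empty site group")
    if background is None:
        background = compute_background(aln, sites)
    f_s = _joint_modal_frequency(aln, sites, background)
    q_s = float(np.prod([background.q[s] for s in sites]))
    q_s = min(max(q_s, 1e-300), 1.0 - 1e-12)
    return binary_relative_entropy(f_s, q_s)


def correlation_entropy(
    aln: Alignment, sites: Sequence[int], background: Background | None = None
) -> float:
    """I_S = D_S - sum over sites of D_i; zero for singletons."""
    sites = list(sites)
    if background is None:
        background = compute_background(aln, sites)
    d_s = group_entropy(aln, sites, background)
    d_i = sum(site_entropy(aln, s, background=background) for s in sites)
    return d_s - d_i


@dataclass(frozen=True)
class IndependenceResult:
    """Outcome of the between-group independence test."""

    theta_obs: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    independent: bool  # True when theta is not significantly non-null
    n_random: int
    overlap: int  # shared sites between g1 and g2 (logged, allowed)


def independence_test(
    aln: Alignment,
    g1: Sequence[int],
    g2: Sequence[int],
    domain_site_pool: Sequence[int],
    n_random: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    background: Background | None = None,
) -> IndependenceResult:
    """Test theta = I_(g1 u g2) - (I_g1 + I_g2) against random same-size groups.

    Null replicates draw two disjoint site sets of sizes |g1| and |g2| from
    ``domain_site_pool``; significance is a two-sided normal test of the
    z-score against the replicate mean and standard deviation.  The verdict
    ``independent`` holds when p >= alpha.
    """
    g1, g2 = sorted(set(g1)), sorted(set(g2))
    pool = sorted(set(domain_site_pool))
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    if n_random < 100:
        raise ValueError("n_random must be at least 100")
    if len(pool) < len(g1) + len(g2):
        raise ValueError(
            f"pool of {len(pool)} sites cannot host disjoint groups of "
            f"{len(g1)} and {len(g2)}"
        )
    needed = sorted(set(g1) | set(g2) | set(pool))
    if background is None:
        background = compute_background(aln, needed)

    def theta(a: Sequence[int], b: Sequence[int]) -> float:
        union = sorted(set(a) | set(b))
        return (
            correlation_entropy(aln, union, background)
            - correlation_entropy(aln, a, background)
            - correlation_entropy(aln, b, background)
        )

    theta_obs = theta(g1, g2)
    rng = np.random.default_rng(int(seed))
    pool_arr = np.array(pool)
    null = np.empty(n_random)
    # theta is symmetric in the groups, so draw null sizes in sorted order
    # to keep the test invariant under swapping g1 and g2
    k1, k2 = sorted((len(g1), len(g2)))
    for t in range(n_random):
        pick = rng.choice(len(pool_arr), size=k1 + k2, replace=False)
        null[t] = theta(pool_arr[pick[:k1]].tolist(), pool_arr[pick[k1:]].tolist())
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate null: zero variance across random groups")
    z = (theta_obs - mean) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return IndependenceResult(
        theta_obs=float(theta_obs),
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        p=p,
        independent=bool(p >= alpha),
        n_random=n_random,
        overlap=len(set(g1) & set(g2)),
    )
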