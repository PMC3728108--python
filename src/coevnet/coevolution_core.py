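"""CAPS-style covariation detection.

The statistic: for one alignment column, score every unordered sequence pair
by the BLOSUM62 value of its residue transition, center those scores at the
column mean, and divide each by the divergence time of the two sequences.  Two
columns coevolve when their score vectors are strongly positively correlated
across sequence pairs.  Significance comes from an empirical null of the same
correlations measured on neutrally evolving alignments simulated on the same
tree (one-tailed: high positive correlation).

Divergence times can be Li-type synonymous distances from a matched CDS
alignment, patristic tree distances, or Poisson-corrected protein distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import GAP, Alignment, Phylogeny
from .preprocess import SiteMap, p_distance_matrix
from . import synthetic_data

DEFAULT_TIME_FLOOR = 1e-4
MIN_PAIR_OVERLAP = 3

_BLOSUM62 = None


def blosum62() -> "substitution_matrices.Array":
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


# ---------------------------------------------------------------------------
# Divergence times


@dataclass(frozen=True)
class DivergenceMatrix:
    """Symmetric non-negative divergence times over sequence pairs."""

    ids: tuple[str, ...]
    matrix: np.ndarray  # floored copy used as divisor
    mode: str  # li_ks | patristic | poisson_protein
    floor: float = DEFAULT_TIME_FLOOR
    saturated_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("divergence matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("divergence times must be non-negative")

    def subset(self, keep_ids: Sequence[str]) -> "DivergenceMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        idx = [index[i] for i in keep_ids]
        return DivergenceMatrix(
            ids=tuple(keep_ids),
            matrix=self.matrix[np.ix_(idx, idx)],
            mode=self.mode,
            floor=self.floor,
            saturated_pairs=self.saturated_pairs,
        )

    def pair_times(self) -> np.ndarray:
        """Times for unordered pairs in row-major (i<j) order, floored."""
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return np.maximum(self.matrix[iu], self.floor)


def _li_ks_pair(cds_a: str, cds_b: str) -> float:
    """Li-type (LWL85) synonymous distance for one in-frame CDS pair.

    Codons gapped or ambiguous in either sequence are dropped pairwise.
    Raises ValueError when the estimate is saturated (log undefined).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    keep_a, keep_b = [], []
    for k in range(0, len(cds_a) - 2, 3):
        ca, cb = cds_a[k : k + 3], cds_b[k : k + 3]
        if "-" in ca or "-" in cb:
            continue
        if not set(ca + cb) <= set("ACGT"):
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    if not keep_a:
        raise ValueError("no comparable codons")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _dn, ds = cal_dn_ds(
            CodonSeq("".join(keep_a)), CodonSeq("".join(keep_b)), method="LWL85"
        )
    if not math.isfinite(ds) or ds < 0:
        raise ValueError(f"degenerate synonymous distance {ds}")
    return float(ds)


def divergence_times(
    aln: Alignment,
    mode: str = "poisson_protein",
    tree: Phylogeny | None = None,
    cds: Alignment | None = None,
    floor: float = DEFAULT_TIME_FLOOR,
) -> DivergenceMatrix:
    """Divergence-time matrix over the alignment's sequence pairs.

    ``li_ks`` needs a matched in-frame CDS alignment (3x protein length, same
    ids); ``patristic`` needs a tree over the alignment ids;
    ``poisson_protein`` uses -ln(1 - p) on pairwise p-distances.  Saturated
    estimates are flagged and replaced by the matrix maximum.
    """
    n = aln.n_sequences
    saturated: list[tuple[str, str]] = []
    if mode == "patristic":
        if tree is None:
            raise ValueError("patristic mode requires a tree")
        m = tree.patristic_matrix(aln.ids)
    elif mode == "poisson_protein":
        p = p_distance_matrix(aln)
        with np.errstate(divide="ignore"):
            m = -np.log(1.0 - p)
        sat = ~np.isfinite(m)
        if sat.any():
            for a, b in zip(*np.where(np.triu(sat, k=1))):
                saturated.append((aln.ids[a], aln.ids[b]))
            m[sat] = np.nan
    elif mode == "li_ks":
        if cds is None:
            raise ValueError("li_ks mode requires a matched CDS alignment")
        if cds.ids != aln.ids:
            raise ValueError("CDS ids must match the protein alignment ids")
        if cds.length != 3 * aln.length:
            raise ValueError(
                f"CDS length {cds.length} is not 3x protein length {aln.length}"
            )
        m = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                try:
                    ks = _li_ks_pair(cds.rows[a], cds.rows[b])
                except (ValueError, ZeroDivisionError, KeyError):
                    saturated.append((aln.ids[a], aln.ids[b]))
                    ks = np.nan
                m[a, b] = m[b, a] = ks
    else:
        raise ValueError(f"unknown divergence mode {mode!r}")

    if np.isnan(m).any():
        finite = m[np.isfinite(m)]
        fill = float(finite.max()) if finite.size else floor
        m = np.where(np.isfinite(m), m, fill)
    np.fill_diagonal(m, 0.0)
    return DivergenceMatrix(
        ids=aln.ids,
        matrix=m,
        mode=mode,
        floor=floor,
        saturated_pairs=tuple(saturated),
    )


# ---------------------------------------------------------------------------
# Site vectors


@dataclass(frozen=True)
class SiteVector:
    """Corrected transition scores of one column over sequence pairs."""

    column: int  # 1-based
    values: np.ndarray  # NaN where the pair is excluded (gap at the site)
    n_included: int


def _residue_index_matrix(aln: Alignment) -> np.ndarray:
    """(n, L) indices into the BLOSUM alphabet; -1 for gaps/unknowns."""
    b = blosum62()
    lookup = np.full(128, -1, dtype=np.int32)
    for k, aa in enumerate(b.alphabet):
        lookup[ord(aa)] = k
    lookup[ord("*")] = -1
    lookup[ord(GAP)] = -1
    codes = np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n_sequences, aln.length)
    return lookup[codes]


def site_vector_matrix(
    aln: Alignment, times: DivergenceMatrix
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """All site vectors at once: (L, n_pairs) matrix, NaN = excluded pair.

    Entry (c, k) for sequence pair k=(s,t): (B(a_s, a_t) - column mean B) / t(s,t).
    """
    if times.ids != aln.ids:
        raise ValueError("divergence matrix ids must match alignment ids")
    b = np.asarray(blosum62())
    idx = _residue_index_matrix(aln)
    n = aln.n_sequences
    iu = np.triu_indices(n, k=1)
    t = times.pair_times()

    left = idx[iu[0], :]  # (n_pairs, L)
    right = idx[iu[1], :]
    valid = (left >= 0) & (right >= 0)
    raw = np.where(valid, b[np.clip(left, 0, None), np.clip(right, 0, None)], np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_mean = np.nanmean(raw, axis=0)  # (L,)
    centered = raw - col_mean[None, :]
    V = (centered / t[:, None]).T  # (L, n_pairs)
    return V, iu


def site_vector(aln: Alignment, column: int, times: DivergenceMatrix) -> SiteVector:
    """Corrected-score vector of one 1-based column."""
    V, _ = site_vector_matrix(aln, times)
    values = V[column - 1]
    n_inc = int(np.isfinite(values).sum())
    if n_inc == 0:
        raise ValueError(f"column {column} has no ungapped sequence pairs")
    return SiteVector(column=column, values=values, n_included=n_inc)


# ---------------------------------------------------------------------------
# Correlations


def pair_correlation(v_i: SiteVector | np.ndarray, v_j: SiteVector | np.ndarray):
    """Pearson correlation over jointly included entries.

    Returns ``(r, None)`` or ``(nan, reason)`` when the pair has fewer than
    three joint entries or a constant vector.
    """
    x = v_i.values if isinstance(v_i, SiteVector) else np.asarray(v_i, dtype=float)
    y = v_j.values if isinstance(v_j, SiteVector) else np.asarray(v_j, dtype=float)
    joint = np.isfinite(x) & np.isfinite(y)
    if joint.sum() < MIN_PAIR_OVERLAP:
        return float("nan"), "insufficient overlap"
    xs, ys = x[joint], y[joint]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), "zero variance"
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, None


def _masked_products(X: np.ndarray, Y: np.ndarray):
    MX = np.isfinite(X)
    MY = np.isfinite(Y)
    Xf = np.where(MX, X, 0.0)
    Yf = np.where(MY, Y, 0.0)
    N = MX.astype(float) @ MY.T.astype(float)
    SX = Xf @ MY.T.astype(float)
    SY = MX.astype(float) @ Yf.T
    SXX = (Xf * Xf) @ MY.T.astype(float)
    SYY = MX.astype(float) @ (Yf * Yf).T
    SXY = Xf @ Yf.T
    return N, SX, SY, SXX, SYY, SXY


def correlation_matrix(
    VA: np.ndarray, VB: np.ndarray | None = None
) -> np.ndarray:
    """NaN-aware Pearson correlations between rows of VA and VB (or VA x VA).

    Entries with fewer than three joint observations or a constant row on the
    joint mask are NaN.
    """
    X = np.asarray(VA, dtype=float)
    Y = X if VB is None else np.asarray(VB, dtype=float)
    N, SX, SY, SXX, SYY, SXY = _masked_products(X, Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_x = N * SXX - SX * SX
        var_y = N * SYY - SY * SY
        cov = N * SXY - SX * SY
        scale_x = np.maximum(SXX, 1.0)
        scale_y = np.maximum(SYY, 1.0)
        bad = (
            (N < MIN_PAIR_OVERLAP)
            | (var_x <= 1e-12 * N * scale_x)
            | (var_y <= 1e-12 * N * scale_y)
        )
        R = cov / np.sqrt(np.maximum(var_x, 1e-300) * np.maximum(var_y, 1e-300))
    R = np.clip(R, -1.0, 1.0)
    R[bad] = np.nan
    return R


def row_pair_correlations(
    V: np.ndarray, ii: np.ndarray, jj: np.ndarray
) -> np.ndarray:
    """Correlations of selected row pairs (vectorized, NaN-aware).

    Fully observed matrices (no gaps anywhere, e.g. simulated alignments)
    take a dense path that reuses per-row sums instead of building masks.
    """
    if not np.isnan(V).any():
        P = V.shape[1]
        sx_all = V.sum(axis=1)
        sxx_all = np.einsum("ij,ij->i", V, V)
        X, Y = V[ii], V[jj]
        sxy = np.einsum("ij,ij->i", X, Y)
        sx, sy = sx_all[ii], sx_all[jj]
        var_x = P * sxx_all[ii] - sx * sx
        var_y = P * sxx_all[jj] - sy * sy
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (P * sxy - sx * sy) / np.sqrt(
                np.maximum(var_x, 1e-300) * np.maximum(var_y, 1e-300)
            )
        bad = (
            (P < MIN_PAIR_OVERLAP)
            | (var_x <= 1e-12 * P * np.maximum(sxx_all[ii], 1.0))
            | (var_y <= 1e-12 * P * np.maximum(sxx_all[jj], 1.0))
        )
        r = np.clip(r, -1.0, 1.0)
        r[bad] = np.nan
        return r
    X = V[ii]
    Y = V[jj]
    MX = np.isfinite(X)
    MY = np.isfinite(Y)
    M = MX & MY
    Xf = np.where(M, X, 0.0)
    Yf = np.where(M, Y, 0.0)
    n = M.sum(axis=1)
    sx = Xf.sum(axis=1)
    sy = Yf.sum(axis=1)
    sxx = (Xf * Xf).sum(axis=1)
    syy = (Yf * Yf).sum(axis=1)
    sxy = (Xf * Yf).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        r = (n * sxy - sx * sy) / np.sqrt(
            np.maximum(var_x, 1e-300) * np.maximum(var_y, 1e-300)
        )
    bad = (
        (n < MIN_PAIR_OVERLAP)
        | (var_x <= 1e-12 * n * np.maximum(sxx, 1.0))
        | (var_y <= 1e-12 * n * np.maximum(syy, 1.0))
    )
    r = np.clip(r, -1.0, 1.0)
    r[bad] = np.nan
    return r


# ---------------------------------------------------------------------------
# Null model


@dataclass(frozen=True)
class NullModel:
    """Empirical null distribution of the pair-correlation statistic."""

    samples: np.ndarray  # sorted ascending
    n_sim_alignments: int
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def threshold(self, alpha: float) -> float:
        """Empirical (1 - alpha) quantile of the null correlations."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return float(np.quantile(self.samples, 1.0 - alpha, method="higher"))

    def exceedance_p(self, r, rng: np.random.Generator | None = None) -> np.ndarray:
        """Upper-tail exceedance probability of each r against the null sample.

        Without ``rng``: the conservative add-one estimator (k + 1) / (n + 1)
        with k counting null values >= r.  With ``rng``: exact randomized
        tie-breaking, p = (#{null > r} + U (#{null == r} + 1)) / (n + 1) with
        U uniform — under exchangeability p is uniformly distributed even when
        the statistic has atoms (the correlation does, at r = 1 exactly, from
        minimally variable column pairs), which the add-one rule cannot give.
        """
        scalar = np.isscalar(r)
        r = np.atleast_1d(np.asarray(r, dtype=float))
        n = self.n_samples
        greater = n - np.searchsorted(self.samples, r, side="right")
        if rng is None:
            ties = n - np.searchsorted(self.samples, r, side="left") - greater
            p = (greater + ties + 1.0) / (n + 1.0)
        else:
            ties = n - np.searchsorted(self.samples, r, side="left") - greater
            u = rng.random(r.shape)
            p = (greater + u * (ties + 1.0)) / (n + 1.0)
        p = np.where(np.isfinite(r), p, np.nan)
        return float(p[0]) if scalar else p


def empirical_frequencies(aln: Alignment) -> np.ndarray:
    """Stationary amino-acid frequencies estimated from an alignment."""
    counts = np.zeros(len(synthetic_data.AMINO_ACIDS))
    index = {aa: k for k, aa in enumerate(synthetic_data.AMINO_ACIDS)}
    for row in aln.rows:
        for c in row:
            k = index.get(c)
            if k is not None:
                counts[k] += 1
    if counts.sum() == 0:
        raise ValueError("alignment contains no standard residues")
    # Laplace smoothing keeps every state reachable in the simulator
    counts += 1.0
    return counts / counts.sum()


def build_null(
    aln: Alignment,
    tree: Phylogeny,
    times: DivergenceMatrix,
    n_sim_alignments: int = 5,
    n_samples: int = 100_000,
    seed: int = 0,
    sim_length: int | None = None,
) -> NullModel:
    """Null correlations from neutral alignments simulated on the same tree.

    Simulated alignments share the tree, the empirical residue frequencies and
    the divergence times of the real data; correlations are pooled over
    randomly chosen column pairs until ``n_samples`` values are collected.
    """
    if set(tree.leaf_labels) != set(aln.ids):
        raise ValueError("tree leaves must equal alignment ids")
    length = sim_length or aln.length
    if length < 10:
        raise ValueError("simulated alignments too short to sample pairs")
    freqs = empirical_frequencies(aln)
    rng = np.random.default_rng(int(seed))
    per_sim = int(np.ceil(n_samples / n_sim_alignments))
    pooled: list[np.ndarray] = []
    n_collected = 0
    for s in range(n_sim_alignments):
        sim_seed = int(rng.integers(2**31 - 1))
        sim_aln, _ = synthetic_data.evolve_alignment(
            tree, length, freqs, (), seed=sim_seed
        )
        sim_aln = sim_aln.subset(list(aln.ids))  # align row order with times
        V, _ = site_vector_matrix(sim_aln, times)
        want = per_sim if s < n_sim_alignments - 1 else n_samples - n_collected
        got: list[np.ndarray] = []
        have = 0
        for _attempt in range(20):
            if have >= want:
                break
            k = max(want - have, 1)
            ii = rng.integers(0, length, size=2 * k)
            jj = rng.integers(0, length, size=2 * k)
            keep = ii != jj
            r = row_pair_correlations(V, ii[keep], jj[keep])
            r = r[np.isfinite(r)][: want - have]
            got.append(r)
            have += len(r)
        pooled.append(np.concatenate(got) if got else np.empty(0))
        n_collected += have
    samples = np.concatenate(pooled)
    if len(samples) < n_samples / 10:
        raise ValueError(
            "too few valid null correlations; simulate longer alignments"
        )
    return NullModel(
        samples=np.sort(samples), n_sim_alignments=n_sim_alignments, seed=int(seed)
    )


# ---------------------------------------------------------------------------
# Detection


@dataclass
class PairResult:
    """A scored candidate coevolving column pair."""

    protein_a: str
    site_a: int
    protein_b: str
    site_b: int
    r: float
    p: float
    significant: bool
    residue_a: int | None = None
    residue_b: int | None = None
    skip_reason: str | None = None
    support: float | None = None
    in_intra_a: bool | None = None  # inter-protein only
    in_intra_b: bool | None = None

    @property
    def key(self) -> tuple[str, int, str, int]:
        return (self.protein_a, self.site_a, self.protein_b, self.site_b)


def _skip_reasons(V: np.ndarray) -> list[str | None]:
    reasons: list[str | None] = []
    for row in V:
        finite = np.isfinite(row)
        if finite.sum() < MIN_PAIR_OVERLAP:
            reasons.append("insufficient overlap")
        elif np.ptp(row[finite]) == 0:
            reasons.append("zero variance")
        else:
            reasons.append(None)
    return reasons


def detect_intra(
    aln: Alignment,
    times: DivergenceMatrix,
    alpha: float,
    null: NullModel,
    site_map: SiteMap | None = None,
    protein: str = "A",
    seed: int = 0,
) -> list[PairResult]:
    """Score every unordered column pair of one alignment against the null.

    ``seed`` drives the randomized tie-breaking of the null exceedance.
    """
    V, _ = site_vector_matrix(aln, times)
    reasons = _skip_reasons(V)
    L = aln.length
    iu = np.triu_indices(L, k=1)
    # same routine as the null sampling, so exact ties compare exactly
    rs = row_pair_correlations(V, iu[0], iu[1])
    ps = null.exceedance_p(rs, rng=np.random.default_rng(int(seed)))
    results: list[PairResult] = []
    for k in range(len(rs)):
        i, j = int(iu[0][k]) + 1, int(iu[1][k]) + 1
        r = float(rs[k])
        skip = reasons[i - 1] or reasons[j - 1]
        if skip is None and not math.isfinite(r):
            skip = "insufficient overlap"
        results.append(
            PairResult(
                protein_a=protein,
                site_a=i,
                protein_b=protein,
                site_b=j,
                r=r,
                p=float(ps[k]),
                significant=bool(skip is None and ps[k] < alpha),
                residue_a=site_map.residue(i) if site_map else None,
                residue_b=site_map.residue(j) if site_map else None,
                skip_reason=skip,
            )
        )
    return results


def detect_inter(
    aln_a: Alignment,
    aln_b: Alignment,
    times: DivergenceMatrix,
    alpha: float,
    null: NullModel,
    site_map_a: SiteMap | None = None,
    site_map_b: SiteMap | None = None,
    protein_a: str = "A",
    protein_b: str = "B",
    intra_sites_a: set[int] | None = None,
    intra_sites_b: set[int] | None = None,
    seed: int = 0,
) -> list[PairResult]:
    """Score all cross-protein column pairs of two organism-paired alignments.

    Both alignments must have identical row order (same organisms).  Each
    result records whether its sites also appeared in intra-protein analyses,
    supporting the indirect-dependency check.
    """
    if aln_a.ids != aln_b.ids:
        raise ValueError(
            "alignments are not organism-paired (ids/order differ)"
        )
    VA, _ = site_vector_matrix(aln_a, times)
    VB, _ = site_vector_matrix(aln_b, times)
    R = correlation_matrix(VA, VB)
    reasons_a = _skip_reasons(VA)
    reasons_b = _skip_reasons(VB)
    ps = null.exceedance_p(R, rng=np.random.default_rng(int(seed)))
    results: list[PairResult] = []
    for i in range(aln_a.length):
        for j in range(aln_b.length):
            r = float(R[i, j])
            skip = reasons_a[i] or reasons_b[j]
            if skip is None and not math.isfinite(r):
                skip = "insufficient overlap"
            results.append(
                PairResult(
                    protein_a=protein_a,
                    site_a=i + 1,
                    protein_b=protein_b,
                    site_b=j + 1,
                    r=r,
                    p=float(ps[i, j]),
                    significant=bool(skip is None and ps[i, j] < alpha),
                    residue_a=site_map_a.residue(i + 1) if site_map_a else None,
                    residue_b=site_map_b.residue(j + 1) if site_map_b else None,
                    skip_reason=skip,
                    in_intra_a=(i + 1) in intra_sites_a
                    if intra_sites_a is not None
                    else None,
                    in_intra_b=(j + 1) in intra_sites_b
                    if intra_sites_b is not None
                    else None,
                )
            )
    return results


def pair_results_table(results: Iterable[PairResult]):
    """Pair results as the standard sorted TSV-ready table."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "protein_a": r.protein_a,
                "site_a": r.site_a,
                "residue_a": r.residue_a,
                "protein_b": r.protein_b,
                "site_b": r.site_b,
                "residue_b": r.residue_b,
                "r": r.r,
                "p": r.p,
                "significant": r.significant,
                "skip_reason": r.skip_reason or "",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_a", "site_a", "residue_a", "protein_b", "site_b",
            "residue_b", "r", "p", "significant", "skip_reason",
        ],
    )
    return table.sort_values(
        ["protein_a", "site_a", "protein_b", "site_b"], kind="mergesort"
    ).reset_index(drop=True)
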