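"""End-to-end orchestration: intra- and inter-protein runs, clade comparison.

One master seed fixes every stochastic stage; stage seeds are derived
deterministically from it, so a rerun with the same config and inputs is
byte-identical.  Every output table travels inside a ResultBundle whose
provenance block records the parameters, derived seeds and input digests.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bootstrap_support, coevolution_core, networks, sectors, structure_analysis
from .coevolution_core import DivergenceMatrix
from .io_formats import Alignment, Phylogeny, ResultBundle, StructureModel
from .preprocess import SiteMap, deduplicate, nj_tree, pair_by_organism


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters with conventional defaults.

    ``caps_internal_resamples`` is accepted for configuration compatibility
    but has no effect on any computation.
    """

    alpha: float = 0.001
    null_samples: int = 100_000
    null_sim_alignments: int = 5
    boot_reps: int = 1000
    boot_fraction: float = 0.8
    boot_null_samples: int = 20_000
    boot_null_sim_alignments: int = 2
    support_threshold: float = 0.70
    n_random_groups: int = 1000
    independence_alpha: float = 0.05
    divergence_mode: str = "patristic"
    annotate_intra: bool = True
    seed: int = 0
    caps_internal_resamples: int | None = None  # accepted, semantically inert

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.boot_fraction < 1:
            raise ValueError("boot_fraction must be in (0, 1)")
        if not 0 <= self.support_threshold <= 1:
            raise ValueError("support_threshold must be in [0, 1]")

    def fast(self) -> "RunConfig":
        """Reduced-effort profile for smoke runs and continuous testing."""
        return replace(
            self,
            null_samples=20_000,
            null_sim_alignments=2,
            boot_reps=50,
            boot_null_samples=5_000,
            boot_null_sim_alignments=1,
            n_random_groups=200,
        )


def _digest(*parts: str) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def _alignment_digest(aln: Alignment) -> str:
    return _digest(*aln.ids, *aln.rows)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _prepare(
    aln: Alignment, tree: Phylogeny | None, config: RunConfig
) -> tuple[Alignment, Phylogeny, DivergenceMatrix]:
    aln = deduplicate(aln)
    if tree is None:
        tree = nj_tree(aln)
    elif set(tree.leaf_labels) != set(aln.ids):
        tree = tree.prune_to(list(aln.ids))
    if config.divergence_mode == "patristic":
        times = coevolution_core.divergence_times(aln, "patristic", tree=tree)
    else:
        times = coevolution_core.divergence_times(aln, config.divergence_mode)
    return aln, tree, times


def _structure_stats(
    structure: StructureModel,
    site_map: SiteMap,
    sites: Sequence[int],
    seed: int,
    n_random: int,
) -> pd.DataFrame:
    """Compactness, cluster significance and SS enrichment for mapped sites."""
    residues = sorted(
        {site_map.residue(s) for s in sites if site_map.residue(s) is not None}
    )
    rows = []
    if len(residues) >= 2:
        compact = structure_analysis.group_compactness(structure, residues)
        pool = list(structure.residue_numbers)
        p_clust = structure_analysis.cluster_significance(
            structure, residues, pool, n_random=max(n_random, 100), seed=seed
        )
        rows.append(
            {"statistic": "group_compactness", "value": compact, "p": p_clust}
        )
        background = structure_analysis.group_compactness(structure, pool)
        rows.append(
            {"statistic": "background_compactness", "value": background, "p": None}
        )
    if residues:
        try:
            enr = structure_analysis.ss_enrichment(structure, residues)
            rows.append(
                {"statistic": "ss_enrichment_chi2", "value": enr.chi2, "p": enr.p}
            )
        except ValueError:
            rows.append(
                {"statistic": "ss_enrichment_chi2", "value": None, "p": None}
            )
    return pd.DataFrame(rows, columns=["statistic", "value", "p"])


def run_intra(
    aln: Alignment,
    tree: Phylogeny | None,
    config: RunConfig,
    site_map: SiteMap | None = None,
    structure: StructureModel | None = None,
    protein: str = "A",
) -> ResultBundle:
    """Full intra-protein analysis: detect, bootstrap, network, structure."""
    aln, tree, times = _prepare(aln, tree, config)
    null = coevolution_core.build_null(
        aln,
        tree,
        times,
        n_sim_alignments=config.null_sim_alignments,
        n_samples=config.null_samples,
        seed=_stage_seed(config.seed, "null"),
    )
    results = coevolution_core.detect_intra(
        aln,
        times,
        config.alpha,
        null,
        site_map=site_map,
        protein=protein,
        seed=_stage_seed(config.seed, "detect"),
    )
    base = [r for r in results if r.significant]
    records = bootstrap_support.bootstrap_pairs(
        aln,
        tree,
        base,
        times=times,
        n_reps=config.boot_reps,
        fraction=config.boot_fraction,
        threshold=config.support_threshold,
        alpha=config.alpha,
        seed=_stage_seed(config.seed, "bootstrap"),
        null_sim_alignments=config.boot_null_sim_alignments,
        null_samples=config.boot_null_samples,
    )
    support_of = {rec.key: rec for rec in records}
    for r in base:
        rec = support_of.get(r.key)
        if rec is not None:
            r.support = rec.support
    retained = [r for r in base if support_of[r.key].retained]
    graph = networks.build_network(retained)
    bundle = ResultBundle(
        pair_table=coevolution_core.pair_results_table(results),
        support_table=bootstrap_support.support_table(records),
        edge_table=networks.edge_table(graph),
        centrality_table=networks.centrality_table(graph),
        provenance={
            "analysis": "intra",
            "protein": protein,
            "config": asdict(config),
            "alignment_digest": _alignment_digest(aln),
            "tree_digest": _digest(tree.to_newick()),
            "n_sequences": aln.n_sequences,
            "n_columns": aln.length,
            "n_significant": len(base),
            "n_retained": len(retained),
            "stage_seeds": {
                s: _stage_seed(config.seed, s) for s in ("null", "bootstrap")
            },
        },
    )
    if structure is not None and site_map is not None:
        sites = sorted({s for r in retained for s in (r.site_a, r.site_b)})
        bundle.structure_table = _structure_stats(
            structure,
            site_map,
            sites,
            seed=_stage_seed(config.seed, "structure"),
            n_random=config.n_random_groups,
        )
    return bundle


def run_inter(
    aln_a: Alignment,
    aln_b: Alignment,
    tree: Phylogeny | None,
    config: RunConfig,
    organism_of_id: Mapping[str, str] | None = None,
    protein_a: str = "A",
    protein_b: str = "B",
) -> ResultBundle:
    """Inter-protein analysis on organism-paired alignments.

    With ``organism_of_id`` the two alignments are intersected and relabeled
    by organism first; otherwise they must already share identical ids.  The
    null is a dedicated cross-protein null simulated under the same model.
    """
    if organism_of_id is not None:
        aln_a, aln_b = pair_by_organism(aln_a, aln_b, organism_of_id, relabel=True)
    if aln_a.ids != aln_b.ids:
        raise ValueError("inter-protein run needs organism-paired alignments")
    combined = Alignment(
        ids=aln_a.ids,
        rows=tuple(ra + rb for ra, rb in zip(aln_a.rows, aln_b.rows)),
        alphabet="protein",
    )
    combined_dedup, tree, times = _prepare(combined, tree, config)
    keep = list(combined_dedup.ids)
    aln_a = aln_a.subset(keep)
    aln_b = aln_b.subset(keep)
    null = coevolution_core.build_null(
        combined_dedup,
        tree,
        times,
        n_sim_alignments=config.null_sim_alignments,
        n_samples=config.null_samples,
        seed=_stage_seed(config.seed, "null-inter"),
    )
    intra_sites_a: set[int] | None = None
    intra_sites_b: set[int] | None = None
    if config.annotate_intra:
        intra_a = coevolution_core.detect_intra(
            aln_a, times, config.alpha, null, protein=protein_a,
            seed=_stage_seed(config.seed, "detect-intra-a"),
        )
        intra_b = coevolution_core.detect_intra(
            aln_b, times, config.alpha, null, protein=protein_b,
            seed=_stage_seed(config.seed, "detect-intra-b"),
        )
        intra_sites_a = {
            s for r in intra_a if r.significant for s in (r.site_a, r.site_b)
        }
        intra_sites_b = {
            s for r in intra_b if r.significant for s in (r.site_a, r.site_b)
        }
    results = coevolution_core.detect_inter(
        aln_a,
        aln_b,
        times,
        config.alpha,
        null,
        protein_a=protein_a,
        protein_b=protein_b,
        intra_sites_a=intra_sites_a,
        intra_sites_b=intra_sites_b,
        seed=_stage_seed(config.seed, "detect-inter"),
    )
    base = [r for r in results if r.significant]
    records = bootstrap_support.bootstrap_pairs(
        aln_a,
        tree,
        base,
        times=times,
        n_reps=config.boot_reps,
        fraction=config.boot_fraction,
        threshold=config.support_threshold,
        alpha=config.alpha,
        seed=_stage_seed(config.seed, "bootstrap-inter"),
        aln_b=aln_b,
        null_sim_alignments=config.boot_null_sim_alignments,
        null_samples=config.boot_null_samples,
    )
    support_of = {rec.key: rec for rec in records}
    retained = [r for r in base if support_of[r.key].retained]
    for r in base:
        r.support = support_of[r.key].support
    graph = networks.build_network(retained)
    pair_table = coevolution_core.pair_results_table(results)
    flags = pd.DataFrame(
        {
            "in_intra_a": [bool(r.in_intra_a) if r.in_intra_a is not None else None
                           for r in results],
            "in_intra_b": [bool(r.in_intra_b) if r.in_intra_b is not None else None
                           for r in results],
            "site_a": [r.site_a for r in results],
            "site_b": [r.site_b for r in results],
        }
    )
    pair_table = pair_table.merge(flags, on=["site_a", "site_b"], how="left")
    return ResultBundle(
        pair_table=pair_table,
        support_table=bootstrap_support.support_table(records),
        edge_table=networks.edge_table(graph),
        centrality_table=networks.centrality_table(graph),
        provenance={
            "analysis": "inter",
            "proteins": [protein_a, protein_b],
            "config": asdict(config),
            "alignment_digest_a": _alignment_digest(aln_a),
            "alignment_digest_b": _alignment_digest(aln_b),
            "n_organisms": aln_a.n_sequences,
            "n_significant": len(base),
            "n_retained": len(retained),
        },
    )


def run_clade_comparison(
    aln: Alignment,
    clade_groups: Mapping[str, Mapping[str, Sequence[int]]],
    domain_pools: Mapping[str, Sequence[int]],
    config: RunConfig,
) -> ResultBundle:
    """Independence tests between clades' coevolving groups, per domain.

    ``clade_groups`` maps clade -> domain -> alignment columns;
    ``domain_pools`` maps domain -> the domain's full column pool.
    Clades with empty groups for a domain are skipped with a notice row.
    """
    rows = []
    clades = sorted(clade_groups)
    rng_seed = _stage_seed(config.seed, "sectors")
    background = sectors.compute_background(aln)
    for k1 in range(len(clades)):
        for k2 in range(k1 + 1, len(clades)):
            c1, c2 = clades[k1], clades[k2]
            for domain in sorted(domain_pools):
                g1 = list(clade_groups.get(c1, {}).get(domain, []))
                g2 = list(clade_groups.get(c2, {}).get(domain, []))
                base = {
                    "clade_1": c1,
                    "clade_2": c2,
                    "domain": domain,
                    "size_1": len(g1),
                    "size_2": len(g2),
                }
                if not g1 or not g2:
                    rows.append({**base, "note": "empty group; skipped"})
                    continue
                try:
                    res = sectors.independence_test(
                        aln,
                        g1,
                        g2,
                        domain_pools[domain],
                        n_random=config.n_random_groups,
                        seed=rng_seed,
                        alpha=config.independence_alpha,
                        background=background,
                    )
                except ValueError as exc:
                    rows.append({**base, "note": str(exc)})
                    continue
                rows.append(
                    {
                        **base,
                        "theta": res.theta_obs,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "z": res.z,
                        "p": res.p,
                        "verdict": "independent" if res.independent else "dependent",
                        "note": "",
                    }
                )
    columns = [
        "clade_1", "clade_2", "domain", "size_1", "size_2",
        "theta", "null_mean", "null_sd", "z", "p", "verdict", "note",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return ResultBundle(
        sector_table=table,
        provenance={
            "analysis": "clade_comparison",
            "config": asdict(config),
            "alignment_digest": _alignment_digest(aln),
            "clades": clades,
            "domains": sorted(domain_pools),
        },
    )
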