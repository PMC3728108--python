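"""Coevolution networks and the three node-centrality measures.

Nodes are sites (protein tag + column, optionally a residue label like
Leu27); edges are retained coevolving pairs with bootstrap support as
metadata.  Shortest paths are hop-based (unweighted): degree is an edge
count, closeness is component-normalized inverse farness, betweenness is the
unnormalized shortest-path pass-through sum over unordered node pairs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd


def build_network(
    pairs: Iterable,
    labels: Mapping[tuple[str, int], str] | None = None,
) -> nx.Graph:
    """Undirected graph from retained pairs.

    ``pairs`` yields objects with protein_a/site_a/protein_b/site_b (and
    optionally ``support``), or plain ((protein, site), (protein, site))
    tuples.  Duplicate edges collapse; self-loops are rejected.
    """
    g = nx.Graph()
    for p in pairs:
        if hasattr(p, "protein_a"):
            a = (p.protein_a, p.site_a)
            b = (p.protein_b, p.site_b)
            support = getattr(p, "support", None)
        else:
            a, b = p
            support = None
        if a == b:
            raise ValueError(f"self-loop at {a}")
        g.add_edge(a, b, support=support)
    if labels:
        nx.set_node_attributes(
            g, {n: labels.get(n, f"{n[0]}:{n[1]}") for n in g}, "label"
        )
    return g


def degree_centrality(g: nx.Graph) -> dict:
    """Number of edges at each node (raw counts, not normalized)."""
    return dict(g.degree())


def closeness_centrality(g: nx.Graph) -> dict:
    """(n_c - 1) / sum of hop distances to same-component peers; 0 if alone."""
    return nx.closeness_centrality(g, wf_improved=False)


def betweenness_centrality(g: nx.Graph) -> dict:
    """Unnormalized shortest-path betweenness over unordered pairs."""
    return nx.betweenness_centrality(g, normalized=False)


def component_labels(g: nx.Graph) -> dict:
    out = {}
    for k, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ):
        for node in comp:
            out[node] = k
    return out


def centrality_table(g: nx.Graph) -> pd.DataFrame:
    """All centralities per node, plus globally normalized closeness."""
    deg = degree_centrality(g)
    clo = closeness_centrality(g)
    clo_norm = nx.closeness_centrality(g, wf_improved=True)
    btw = betweenness_centrality(g)
    comp = component_labels(g)
    rows = [
        {
            "protein": n[0],
            "site": n[1],
            "node": g.nodes[n].get("label", f"{n[0]}:{n[1]}"),
            "degree": deg[n],
            "closeness": clo[n],
            "closeness_normalized": clo_norm[n],
            "betweenness": btw[n],
            "component": comp[n],
        }
        for n in g
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "protein", "site", "node", "degree", "closeness",
            "closeness_normalized", "betweenness", "component",
        ],
    )
    return table.sort_values(["protein", "site"], kind="mergesort").reset_index(
        drop=True
    )


def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for a, b, data in g.edges(data=True):
        a, b = sorted([a, b])
        rows.append(
            {
                "node_a": f"{a[0]}:{a[1]}",
                "node_b": f"{b[0]}:{b[1]}",
                "support": data.get("support"),
            }
        )
    table = pd.DataFrame(rows, columns=["node_a", "node_b", "support"])
    return table.sort_values(["node_a", "node_b"], kind="mergesort").reset_index(
        drop=True
    )
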