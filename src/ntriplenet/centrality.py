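"""Five node centralities (cytoHubba-style) and top-k-intersection hub picks.

* BC     — shortest-path betweenness (unnormalized pair counts).
* Clo    — harmonic closeness, sum of 1/d(v, u) with 1/inf = 0.
* Degree — incident edge count.
* EPC    — edge-percolated component: mean number of other nodes reachable
           from v when each edge is kept independently with probability p.
* RAD    — radiality: sum over reachable u of (D + 1 - d(v, u)) / (n_c - 1),
           with D the diameter and n_c the order of v's component.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

METHODS = ("BC", "Clo", "Degree", "EPC", "RAD")


def compute_centralities(
    graph: nx.Graph,
    epc_realizations: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Centrality table (nodes x five methods) for a simple undirected graph."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("a simple undirected graph is required")
    nodes = sorted(graph.nodes())
    if not nodes:
        raise ValueError("empty graph")

    bc = nx.betweenness_centrality(graph, normalized=False)
    clo = nx.harmonic_centrality(graph)
    deg = dict(graph.degree())

    rad = {v: 0.0 for v in nodes}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        nc = len(comp)
        if nc == 1:
            continue
        sub = graph.subgraph(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(d for row in dist.values() for d in row.values())
        for v in comp:
            rad[v] = sum(diam + 1 - d for u, d in dist[v].items() if u != v) / (nc - 1)

    epc = _edge_percolated_component(graph, nodes, epc_realizations,
                                     epc_keep_prob, seed)
    return pd.DataFrame(
        {
            "BC": [bc[v] for v in nodes],
            "Clo": [clo[v] for v in nodes],
            "Degree": [float(deg[v]) for v in nodes],
            "EPC": [epc[v] for v in nodes],
            "RAD": [rad[v] for v in nodes],
        },
        index=nodes,
    )


def _edge_percolated_component(graph, nodes, realizations, keep_prob, seed):
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges())
    index = {v: i for i, v in enumerate(nodes)}
    totals = np.zeros(len(nodes))
    for _ in range(realizations):
        keep = rng.random(len(edges)) < keep_prob
        parent = np.arange(len(nodes))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for (u, v), k in zip(edges, keep):
            if k:
                ru, rv = find(index[u]), find(index[v])
                if ru != rv:
                    parent[ru] = rv
        roots = np.array([find(i) for i in range(len(nodes))])
        _, inv, counts = np.unique(roots, return_inverse=True, return_counts=True)
        totals += counts[inv] - 1  # reachable nodes exclude v itself
    return {v: totals[index[v]] / realizations for v in nodes}


def select_hub_nodes(table: pd.DataFrame, k: int = 15) -> set[str]:
    """Nodes in the top k of every method, ties at rank k included.

    Including ties keeps the hub set invariant to node ordering.
    """
    if table.empty:
        raise ValueError("empty centrality table")
    hubs = None
    for method in METHODS:
        scores = table[method]
        kth = scores.sort_values(ascending=False).iloc[min(k, len(scores)) - 1]
        top = set(scores.index[scores >= kth])
        hubs = top if hubs is None else hubs & top
    return hubs
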