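"""Global and node-level network topology statistics.

Covers the descriptors reported per network: node/edge counts by sign,
mean degree, clustering coefficient (mean local, with global
transitivity available), characteristic path length over connected
pairs, density, and Louvain module count/modularity — plus normalized
betweenness for hub detection.  Edge signs are ignored for topology:
the graph is treated as simple and unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datatypes import AssociationNetwork


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_edges_pos: int
    n_edges_neg: int
    mean_degree: float
    clustering_coefficient: float
    path_length: float
    density: float
    n_modules: int
    modularity: float


def _as_graph(net: AssociationNetwork | nx.Graph) -> nx.Graph:
    g = net.to_networkx() if isinstance(net, AssociationNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    return g


def mean_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over *connected* node pairs only."""
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        pairs += sub.number_of_nodes() * (sub.number_of_nodes() - 1)
    return total / pairs if pairs else float("nan")


def louvain_modules(
    net: AssociationNetwork | nx.Graph,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[dict[str, int], float]:
    """Best-of-restarts Louvain partition and its Newman modularity Q."""
    g = _as_graph(net)
    best_part: list[set] | None = None
    best_q = -np.inf
    for r in range(n_restarts):
        part = nx.community.louvain_communities(g, seed=seed + r, resolution=1.0)
        q = nx.community.modularity(g, part)
        if q > best_q:
            best_q, best_part = q, part
    assert best_part is not None
    mapping = {}
    for idx, comm in enumerate(sorted(best_part, key=lambda c: sorted(c)[0])):
        for node in comm:
            mapping[node] = idx
    return mapping, float(best_q)


def node_betweenness(
    net: AssociationNetwork | nx.Graph, normalized: bool = True
) -> dict[str, float]:
    """Shortest-path betweenness centrality per node.

    Normalization divides by (N-1)(N-2)/2, the number of orderable pairs
    a node could mediate in an undirected graph.
    """
    g = _as_graph(net)
    return nx.betweenness_centrality(g, normalized=normalized)


def global_topology(
    net: AssociationNetwork | nx.Graph,
    seed: int = 0,
    n_restarts: int = 10,
    clustering: str = "mean_local",
) -> TopologySummary:
    """Table-style global topology of one network.

    ``clustering`` selects mean local clustering (nodes of degree < 2
    contribute 0) or global ``transitivity``.
    """
    g = _as_graph(net)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if isinstance(net, AssociationNetwork):
        pos, neg = net.edge_counts_by_sign()
    else:
        pos, neg = e, 0
    if clustering == "mean_local":
        cc = float(np.mean(list(nx.clustering(g).values())))
    elif clustering == "transitivity":
        cc = float(nx.transitivity(g))
    else:
        raise ValueError(f"unknown clustering flavor {clustering!r}")
    part, q = louvain_modules(g, seed=seed, n_restarts=n_restarts)
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        n_edges_pos=pos,
        n_edges_neg=neg,
        mean_degree=2.0 * e / n,
        clustering_coefficient=cc,
        path_length=mean_path_length(g),
        density=2.0 * e / (n * (n - 1)) if n > 1 else float("nan"),
        n_modules=len(set(part.values())),
        modularity=q,
    )
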