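"""Comparative analysis across group-specific networks.

Edges are the observations: similarity between two networks is the
Jaccard index over their sign-aware canonical edge sets, networks are
clustered on 1 - J, Venn-style region counts summarise sharing, the
core network is the sign-aware intersection across all groups, and a
label-shuffling permutation test (topology preserved exactly) asks
whether two networks share more edges than chance expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import AssociationNetwork, Edge, canonical_edge


def edge_jaccard(nets: dict[str, AssociationNetwork]) -> pd.DataFrame:
    """Pairwise Jaccard similarity of edge sets; NaN when both empty."""
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    names = list(nets)
    sets = {n: nets[n].edge_keys() for n in names}
    J = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in combinations(names, 2):
        union = sets[a] | sets[b]
        J.loc[a, b] = J.loc[b, a] = (
            len(sets[a] & sets[b]) / len(union) if union else np.nan
        )
    for n in names:
        J.loc[n, n] = 1.0 if sets[n] else np.nan
    return J


def cluster_networks(
    simmatrix: pd.DataFrame, linkage: str = "complete"
) -> np.ndarray:
    """Agglomerative clustering of networks on distance 1 - J.

    Returns the scipy linkage matrix (deterministic); leaves follow the
    similarity matrix's row order.
    """
    d = 1.0 - simmatrix.values
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method=linkage)


def shared_edge_counts(nets: dict[str, AssociationNetwork]) -> dict[frozenset, int]:
    """Edge counts for every non-empty membership region (Venn regions).

    Keys are frozensets of network names; the region counts partition
    the union of all edge sets.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    if len(nets) > 6:
        raise ValueError("more than 6 networks: region count explodes")
    sets = {n: net.edge_keys() for n, net in nets.items()}
    union = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for e in union:
        key = frozenset(n for n, s in sets.items() if e in s)
        regions[key] = regions.get(key, 0) + 1
    return regions


def intersect_networks(nets: dict[str, AssociationNetwork]) -> AssociationNetwork:
    """Sign-aware core: edges present in every network.

    Per-edge score is the mean of the per-network consensus scores;
    p/q are not carried over (they are per-network quantities).
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    keysets = [n.edge_keys() for n in nets.values()]
    core_keys = set.intersection(*keysets)
    edges = []
    taxonomy: dict[str, str] = {}
    for key in sorted(core_keys):
        a, b, sign = key
        scores = []
        for net in nets.values():
            for e in net.edges:
                if e.key == key:
                    scores.append(e.score)
                    break
            taxonomy.setdefault(a, net.taxonomy.get(a, ""))
            taxonomy.setdefault(b, net.taxonomy.get(b, ""))
        edges.append(Edge(a, b, sign, float(np.mean(scores)), np.nan, np.nan))
    return AssociationNetwork(edges=edges, taxonomy=taxonomy, name="core")


@dataclass(frozen=True)
class SharedEdgeTest:
    observed: int
    p_value: float
    n_perm: int
    null_mean: float


def shared_edge_permutation_test(
    net_a: AssociationNetwork,
    net_b: AssociationNetwork,
    n_perm: int = 999,
    seed: int | None = None,
) -> SharedEdgeTest:
    """Are more edges shared between two networks than chance expects?

    Null: uniformly shuffle ``net_b``'s node labels among its own nodes
    (degree sequence and topology preserved exactly) and recount the
    sign-aware shared edges.  One-sided p with the +1 correction counts
    null counts >= observed.
    """
    if n_perm < 99:
        import warnings

        warnings.warn("n_perm < 99 gives a very coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    keys_a = net_a.edge_keys()
    edges_b = [(e.otu_a, e.otu_b, e.sign) for e in net_b.edges]
    nodes_b = net_b.node_ids
    observed = len(keys_a & net_b.edge_keys())
    null_counts = np.empty(n_perm, dtype=int)
    for t in range(n_perm):
        perm = rng.permutation(len(nodes_b))
        relabel = {nodes_b[i]: nodes_b[perm[i]] for i in range(len(nodes_b))}
        count = 0
        for a, b, sign in edges_b:
            if canonical_edge(relabel[a], relabel[b], sign) in keys_a:
                count += 1
        null_counts[t] = count
    p = (np.sum(null_counts >= observed) + 1) / (n_perm + 1)
    return SharedEdgeTest(observed, float(p), n_perm, float(null_counts.mean()))
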