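"""k-clique percolation communities on residue interaction networks.

A k-clique community is the union of all k-cliques reachable from one
another through adjacent cliques.  The classical clique-percolation rule
makes two k-cliques adjacent when they share k-1 nodes; this module also
supports the relaxed rule in which sharing k-1 *or* k-2 nodes suffices
(the default here), which merges communities connected through slightly
looser clique overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .psn_graph import ContactNetwork

__all__ = [
    "CommunitySet",
    "enumerate_k_cliques",
    "clique_percolation",
    "stable_communities",
    "min_shared_for_rule",
]

_RULES = ("k-1", "k-2", "either")


def min_shared_for_rule(k: int, rule: str) -> int:
    """Minimum clique-intersection size implied by an adjacency rule."""
    if rule == "k-1":
        return k - 1
    if rule in ("k-2", "either"):
        # "share k-1 or k-2 nodes" == intersection of at least k-2
        return k - 2
    raise ValueError(f"unknown adjacency rule {rule!r}; use one of {_RULES}")


@dataclass
class CommunitySet:
    k: int
    rule: str
    communities: list[frozenset]            # node sets, each >= k nodes
    member_cliques: list[list[frozenset]]   # cliques composing each community
    #: fraction of snapshots in which all of a community's edges are
    #: simultaneously present (NaN when no snapshot data was supplied)
    simultaneous_presence: list[float] | None = None

    @property
    def n_communities(self) -> int:
        return len(self.communities)


def _as_graph(network: ContactNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, ContactNetwork) else network


def enumerate_k_cliques(
    network: ContactNetwork | nx.Graph, k: int
) -> list[frozenset]:
    """All complete subgraphs of exactly size k, each reported once.

    Walks the maximal cliques (Bron–Kerbosch with pivoting via
    networkx) and expands each into its size-k subcliques; every
    k-clique lies inside some maximal clique, so this is exhaustive.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    graph = _as_graph(network)
    found: set[frozenset] = set()
    for maximal in nx.find_cliques(graph):
        if len(maximal) < k:
            continue
        for sub in combinations(sorted(maximal), k):
            found.add(frozenset(sub))
    return sorted(found, key=lambda c: tuple(sorted(c)))


def clique_percolation(
    cliques: list[frozenset], k: int, rule: str = "either"
) -> CommunitySet:
    """Communities as connected components of the clique-adjacency graph.

    Two cliques are adjacent iff their intersection size meets the rule;
    a community's node set is the union of its member cliques, so the
    union-of-k-cliques closure holds by construction.
    """
    min_shared = min_shared_for_rule(k, rule)
    cliques = list(cliques)
    for c in cliques:
        if len(c) != k:
            raise ValueError(f"clique {sorted(c)} does not have size {k}")
    n = len(cliques)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # node -> clique indices for candidate pruning
    by_node: dict = {}
    for i, c in enumerate(cliques):
        for node in c:
            by_node.setdefault(node, []).append(i)
    for i, c in enumerate(cliques):
        candidates = {j for node in c for j in by_node[node] if j > i}
        for j in candidates:
            if len(c & cliques[j]) >= min_shared:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    communities, members = [], []
    for idx_list in groups.values():
        node_set = frozenset().union(*(cliques[i] for i in idx_list))
        communities.append(node_set)
        members.append([cliques[i] for i in idx_list])
    ordered = sorted(
        zip(communities, members), key=lambda t: tuple(sorted(t[0]))
    )
    communities = [c for c, _ in ordered]
    members = [m for _, m in ordered]
    return CommunitySet(
        k=k, rule=rule, communities=communities, member_cliques=members
    )


def _community_presence_fraction(
    community_cliques: list[frozenset],
    presence: np.ndarray,
    index: dict,
) -> float:
    """Fraction of snapshots where every member-clique edge exists at once."""
    edges = set()
    for clique in community_cliques:
        for u, v in combinations(sorted(clique), 2):
            edges.add((index[u], index[v]))
    if not edges:
        return float("nan")
    mask = np.ones(presence.shape[0], dtype=bool)
    for i, j in edges:
        mask &= presence[:, i, j]
    return float(mask.mean())


def stable_communities(
    network: ContactNetwork,
    k: int,
    rule: str = "either",
    occupancy_threshold: float | None = None,
) -> CommunitySet:
    """Communities of the occupancy-stable edge network of an ensemble.

    Cliques and communities are computed on the edges whose occupancy
    strictly exceeds the threshold; when per-snapshot presence data is
    available each community additionally reports the fraction of
    snapshots in which all its member-clique edges are simultaneously
    present, so the stricter whole-subgraph reading of dynamic stability
    stays inspectable.
    """
    if occupancy_threshold is not None:
        import dataclasses

        network = dataclasses.replace(
            network,
            config=dataclasses.replace(
                network.config, occupancy_threshold=occupancy_threshold
            ),
        )
    stable = network.stable_network()
    cliques = enumerate_k_cliques(stable, k)
    result = clique_percolation(cliques, k, rule)
    if network.presence is not None:
        index = {key: i for i, key in enumerate(network.residue_keys)}
        result.simultaneous_presence = [
            _community_presence_fraction(mc, network.presence, index)
            for mc in result.member_cliques
        ]
    return result
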