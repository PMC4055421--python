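"""Correlation-weighted communication graphs, centrality and pathways.

Edges of the dynamically stable contact network are weighted by how much
dynamic information flows through them:

    w_ij = -ln |C_ij|,

so strongly correlated contacts are "short" and near-independent ones
"long".  Shortest paths under these weights (all pairs, Floyd–Warshall
with minimum-weight path counting) yield normalized betweenness
profiles; residues with high betweenness sit on many communication
routes and are candidate mediators of allosteric signalling.  For a
chosen source/target pair the module enumerates the optimal path plus
all suboptimal paths within a length tolerance (default 0.69, the
weight of a C = 0.5 edge), restricted to sufficiently correlated
intermediates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationMatrix
from .psn_graph import ContactNetwork

__all__ = [
    "CommGraph",
    "PathEnsemble",
    "edge_weight",
    "build_comm_graph",
    "all_pairs_shortest_paths",
    "degree_centrality",
    "betweenness",
    "closeness",
    "suboptimal_paths",
]

#: default suboptimal-path tolerance: weight of a C = 0.5 edge
DEFAULT_TOLERANCE = 0.69

_TIE_RTOL = 1e-9


def edge_weight(c_ij: float, floor: float = 1e-6) -> float:
    """Information-flow weight w = -ln max(|C|, floor).

    Perfectly correlated pairs cost nothing to traverse (w = 0);
    uncorrelated pairs are capped at -ln(floor) instead of infinity so
    the graph stays finite.
    """
    c = abs(float(c_ij))
    if c > 1.0 + 1e-9:
        raise ValueError(f"|C_ij| = {c} exceeds 1")
    return -float(np.log(max(min(c, 1.0), floor)))


@dataclass
class CommGraph:
    """Weighted communication graph over stable contact edges.

    ``graph`` carries per-edge ``weight``, source ``C`` and a ``weak``
    flag (|C| below ``c_min``); ``path_graph`` drops the weak edges and
    is what explicit source-to-target path searches run on, while
    centrality uses the full graph so weak contacts still carry
    (heavily penalized) flow.
    """

    graph: nx.Graph
    c_min: float
    floor: float = 1e-6

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def path_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, data in self.graph.edges(data=True):
            if not data.get("weak", False):
                g.add_edge(u, v, **data)
        return g


def build_comm_graph(
    stable: ContactNetwork,
    correlation: CorrelationMatrix,
    c_min: float = 0.5,
    floor: float = 1e-6,
) -> CommGraph:
    """Attach correlation weights to the stable contact edges.

    An edge is never created where there is no stable contact, whatever
    the correlation; contacts whose |C| falls below ``c_min`` are kept
    for centrality but flagged weak and excluded from explicit path
    ensembles.
    """
    lookup = correlation.lookup()
    missing = [n for n in stable.graph.nodes if n not in lookup]
    if missing:
        raise ValueError(
            f"nodes missing from the correlation matrix: {missing[:5]}"
        )
    g = nx.Graph()
    g.add_nodes_from(stable.graph.nodes)
    for u, v, data in stable.graph.edges(data=True):
        c = float(correlation.matrix[lookup[u], lookup[v]])
        g.add_edge(
            u, v,
            weight=edge_weight(c, floor),
            C=c,
            weak=abs(c) < c_min,
            **{k: val for k, val in data.items() if k in ("occupancy", "I")},
        )
    return CommGraph(graph=g, c_min=c_min, floor=floor)


# ---------------------------------------------------------------------------
# All-pairs shortest paths with path counting (Floyd–Warshall)


def _weight_matrix(graph: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for u, v, data in graph.edges(data=True):
        weight = float(data.get("weight", 1.0))
        if weight < 0:
            raise ValueError(f"negative edge weight on {u}-{v}")
        i, j = index[u], index[v]
        w[i, j] = w[j, i] = min(w[i, j], weight)
    return nodes, w


def all_pairs_shortest_paths(
    graph: CommGraph | nx.Graph,
) -> tuple[list, np.ndarray, np.ndarray]:
    """Exact all-pairs distances and minimum-weight path counts.

    Floyd–Warshall over the weighted graph; at stage k a pair's count
    accumulates the product of counts through k exactly when the detour
    ties the incumbent within a relative tolerance of 1e-9.  Returns
    (nodes, distance matrix, count matrix); disconnected pairs have
    infinite distance and count 0.
    """
    g = graph.graph if isinstance(graph, CommGraph) else graph
    nodes, dist = _weight_matrix(g)
    n = len(nodes)
    counts = np.where(np.isfinite(dist) & (dist > 0), 1.0, 0.0)
    np.fill_diagonal(counts, 1.0)
    # direct zero-weight edges still count as one path
    for u, v, data in g.edges(data=True):
        i = nodes.index(u)
        j = nodes.index(v)
        counts[i, j] = counts[j, i] = 1.0
    active = np.ones(n, dtype=bool)
    for k in range(n):
        dk = dist[:, k][:, None] + dist[k, :][None, :]
        ck = counts[:, k][:, None] * counts[k, :][None, :]
        tol = _TIE_RTOL * np.maximum(
            np.where(np.isfinite(dist), np.abs(dist), 1.0), 1.0
        )
        with np.errstate(invalid="ignore"):
            better = (dk < dist - tol) | (
                np.isfinite(dk) & ~np.isfinite(dist)
            )
            equal = np.abs(dk - dist) <= tol
        # k must be a strict intermediate: exclude its own row/column and
        # the diagonal
        mask = np.ones((n, n), dtype=bool)
        mask[k, :] = False
        mask[:, k] = False
        np.fill_diagonal(mask, False)
        upd = better & mask & np.isfinite(dk)
        dist[upd] = dk[upd]
        counts[upd] = ck[upd]
        add = equal & mask & np.isfinite(dk)
        counts[add] += ck[add]
    counts[~np.isfinite(dist)] = 0.0
    return nodes, dist, counts


def degree_centrality(network: ContactNetwork) -> pd.DataFrame:
    """Degree D_i = sum_j a_ij of the contact adjacency matrix."""
    a = network.adjacency()
    deg = a.sum(axis=1)
    return pd.DataFrame(
        {
            "chain": [k[0] for k in network.residue_keys],
            "residue": [f"{k[1]}{k[2]}" for k in network.residue_keys],
            "res_name": network.residue_names,
            "degree": deg,
        }
    )


def betweenness(graph: CommGraph | nx.Graph) -> dict[Hashable, float]:
    """Normalized shortest-path betweenness of every node.

    b_i = sum over unordered pairs (j, k), j != i != k, of the fraction
    of minimum-weight j-k paths passing through i, divided by
    (N-1)(N-2)/2.  Endpoints are never counted as pass-through.
    """
    nodes, dist, counts = all_pairs_shortest_paths(graph)
    n = len(nodes)
    if n < 3:
        warnings.warn("betweenness undefined for fewer than 3 nodes")
        return {node: 0.0 for node in nodes}
    raw = np.zeros(n)
    tol = _TIE_RTOL * np.maximum(
        np.where(np.isfinite(dist), np.abs(dist), 1.0), 1.0
    )
    for i in range(n):
        with np.errstate(invalid="ignore"):
            through = (
                np.abs(dist[:, i][:, None] + dist[i, :][None, :] - dist)
                <= tol
            )
        through &= np.isfinite(dist)
        valid = counts > 0
        jj, kk = np.where(np.triu(through & valid, k=1))
        keep = (jj != i) & (kk != i)
        jj, kk = jj[keep], kk[keep]
        raw[i] = np.sum(counts[jj, i] * counts[i, kk] / counts[jj, kk])
    norm = (n - 1) * (n - 2) / 2.0
    return {node: float(raw[i] / norm) for i, node in enumerate(nodes)}


def closeness(graph: CommGraph | nx.Graph) -> dict[Hashable, float]:
    """Inverse mean shortest-path distance to all reachable nodes."""
    nodes, dist, _ = all_pairs_shortest_paths(graph)
    out: dict[Hashable, float] = {}
    for i, node in enumerate(nodes):
        finite = np.isfinite(dist[i]) & (np.arange(len(nodes)) != i)
        out[node] = (
            float(finite.sum() / dist[i, finite].sum())
            if finite.any() and dist[i, finite].sum() > 0
            else 0.0
        )
    return out


# ---------------------------------------------------------------------------
# Suboptimal path ensembles


@dataclass
class PathEnsemble:
    source: Hashable
    target: Hashable
    optimal_length: float
    tolerance: float
    paths: list[tuple[list, float]] = field(default_factory=list)
    truncated: bool = False
    disconnected: bool = False

    @property
    def optimal_path(self) -> list | None:
        return self.paths[0][0] if self.paths else None

    def lengths(self) -> list[float]:
        return [length for _, length in self.paths]


def suboptimal_paths(
    graph: CommGraph | nx.Graph,
    source: Hashable,
    target: Hashable,
    tolerance: float = DEFAULT_TOLERANCE,
    max_paths: int = 100_000,
) -> PathEnsemble:
    """All simple paths within ``tolerance`` of the optimal length.

    Depth-first search with branch-and-bound: a partial path is pruned
    as soon as its length plus the remaining shortest distance to the
    target exceeds the budget L_opt + tolerance.  Enumeration stops
    (flagged ``truncated``) at ``max_paths``.  When the graph is a
    CommGraph, weak (|C| < c_min) edges are excluded, following the
    restriction of communication pathways to correlated intermediates.
    """
    if source == target:
        raise ValueError("source and target must differ")
    g = graph.path_graph() if isinstance(graph, CommGraph) else graph
    if source not in g or target not in g:
        raise ValueError("source or target not in graph")
    try:
        to_target = nx.single_source_dijkstra_path_length(
            g, target, weight="weight"
        )
    except nx.NodeNotFound:  # pragma: no cover
        to_target = {}
    if source not in to_target:
        return PathEnsemble(
            source=source, target=target, optimal_length=float("inf"),
            tolerance=tolerance, disconnected=True,
        )
    l_opt = to_target[source]
    budget = l_opt + tolerance + 1e-12
    found: list[tuple[list, float]] = []
    truncated = False

    stack: list[tuple[Hashable, float, list, set]] = [
        (source, 0.0, [source], {source})
    ]
    while stack:
        node, length, path, visited = stack.pop()
        if node == target:
            found.append((path, length))
            if len(found) >= max_paths:
                truncated = True
                break
            continue
        for nbr in g.neighbors(node):
            if nbr in visited:
                continue
            w = float(g[node][nbr].get("weight", 1.0))
            new_len = length + w
            bound = to_target.get(nbr, float("inf"))
            if new_len + bound > budget:
                continue
            stack.append((nbr, new_len, path + [nbr], visited | {nbr}))
    found.sort(key=lambda t: (t[1], t[0]))
    return PathEnsemble(
        source=source, target=target, optimal_length=l_opt,
        tolerance=tolerance, paths=found, truncated=truncated,
    )


def hop_count_paths(
    graph: CommGraph | nx.Graph, source: Hashable, target: Hashable
) -> list[list]:
    """Unweighted shortest paths (every edge counts one), the first-stage
    cross-check before weighted paths are taken as authoritative."""
    g = graph.graph if isinstance(graph, CommGraph) else graph
    try:
        return [list(p) for p in nx.all_shortest_paths(g, source, target)]
    except nx.NetworkXNoPath:
        return []
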