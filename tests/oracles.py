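"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — double loops, exhaustive
enumeration — and shares no code path with the implementations it
checks.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def naive_force_constants(
    frames: np.ndarray,
    chain_pos: np.ndarray,
    chains: np.ndarray,
    exclusion_width: int = 1,
    energy: float = 3.0 * 1.987204259e-3 * 300.0,
) -> np.ndarray:
    """Two-pass, all-loops force constants for one-atom-per-residue
    ensembles.  frames: (F, N, 3)."""
    n_frames, n_res, _ = frames.shape
    d = np.zeros((n_frames, n_res))
    for f in range(n_frames):
        for i in range(n_res):
            total, count = 0.0, 0
            for j in range(n_res):
                if i == j:
                    continue
                if chains[i] == chains[j] and abs(
                    int(chain_pos[i]) - int(chain_pos[j])
                ) <= exclusion_width:
                    continue
                total += float(np.linalg.norm(frames[f, i] - frames[f, j]))
                count += 1
            d[f, i] = total / count
    k = np.empty(n_res)
    for i in range(n_res):
        mean = sum(d[f, i] for f in range(n_frames)) / n_frames
        var = sum((d[f, i] - mean) ** 2 for f in range(n_frames)) / n_frames
        k[i] = energy / var if var > 0 else np.inf
    return k


def all_k_cliques(graph: nx.Graph, k: int) -> set[frozenset]:
    """Every size-k complete subgraph by checking all node subsets."""
    out = set()
    for nodes in combinations(sorted(graph.nodes), k):
        if all(graph.has_edge(u, v) for u, v in combinations(nodes, 2)):
            out.add(frozenset(nodes))
    return out


def percolation_communities(
    cliques: list[frozenset], min_shared: int
) -> set[frozenset]:
    """Connected components of the clique-adjacency relation, by BFS."""
    cliques = list(cliques)
    n = len(cliques)
    unvisited = set(range(n))
    communities = set()
    while unvisited:
        start = unvisited.pop()
        stack, members = [start], set(cliques[start])
        while stack:
            cur = stack.pop()
            hits = [
                j for j in unvisited
                if len(cliques[cur] & cliques[j]) >= min_shared
            ]
            for j in hits:
                unvisited.discard(j)
                members |= cliques[j]
            stack.extend(hits)
        communities.add(frozenset(members))
    return communities


def enumerate_simple_paths(
    graph: nx.Graph, source, target
) -> list[tuple[list, float]]:
    """All simple source->target paths with their total weights."""
    out: list[tuple[list, float]] = []

    def dfs(node, length, path, visited):
        if node == target:
            out.append((list(path), length))
            return
        for nbr in graph.neighbors(node):
            if nbr in visited:
                continue
            visited.add(nbr)
            path.append(nbr)
            dfs(nbr, length + float(graph[node][nbr].get("weight", 1.0)),
                path, visited)
            path.pop()
            visited.discard(nbr)

    dfs(source, 0.0, [source], {source})
    return out


def shortest_path_stats(
    graph: nx.Graph, rtol: float = 1e-9
) -> tuple[dict, dict]:
    """Exhaustive all-pairs shortest distances and minimum-weight path
    counts from full simple-path enumeration."""
    nodes = list(graph.nodes)
    dist: dict = {}
    count: dict = {}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            paths = enumerate_simple_paths(graph, u, v)
            if not paths:
                dist[(u, v)] = float("inf")
                count[(u, v)] = 0
                continue
            best = min(length for _, length in paths)
            tol = rtol * max(abs(best), 1.0)
            dist[(u, v)] = best
            count[(u, v)] = sum(
                1 for _, length in paths if abs(length - best) <= tol
            )
    return dist, count


def exhaustive_betweenness(graph: nx.Graph, rtol: float = 1e-9) -> dict:
    """Normalized betweenness by enumerating every shortest path."""
    nodes = list(graph.nodes)
    n = len(nodes)
    raw = {node: 0.0 for node in nodes}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            paths = enumerate_simple_paths(graph, u, v)
            if not paths:
                continue
            best = min(length for _, length in paths)
            tol = rtol * max(abs(best), 1.0)
            shortest = [p for p, length in paths if abs(length - best) <= tol]
            for node in nodes:
                if node in (u, v):
                    continue
                through = sum(1 for p in shortest if node in p)
                raw[node] += through / len(shortest)
    norm = (n - 1) * (n - 2) / 2.0
    return {node: value / norm for node, value in raw.items()}


def random_weighted_graph(
    n: int, p: float, seed: int, connected: bool = False
) -> nx.Graph:
    rng = np.random.default_rng(seed)
    while True:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    g.add_edge(i, j, weight=float(rng.uniform(0.1, 2.0)))
        if not connected or nx.is_connected(g):
            return g
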