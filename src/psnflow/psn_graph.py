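"""Residue interaction networks from side-chain contacts.

Residues are nodes; an edge connects residues i and j when their
normalized side-chain contact strength

    I_ij = 100 * n_ij / sqrt(N_i * N_j)   (percent)

exceeds a cutoff I_min, where n_ij counts distinct side-chain heavy-atom
pairs within 4.5 A and N_i is a residue-type normalization (the maximal
contact capacity of that residue type).  Sequence neighbours within a
chain are never connected — their contacts are covalent trivia, not
tertiary interactions.  Over an ensemble, an edge's occupancy is the
fraction of snapshots in which it exists; edges above 0.75 occupancy
form the dynamically stable network that all downstream community and
centrality analysis runs on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble_io import (
    ConformationalEnsemble,
    ResidueKey,
    ResidueSelection,
    Structure,
    select_residue_atoms,
)

__all__ = [
    "DEFAULT_NORMALIZATION",
    "PsnConfig",
    "ContactNetwork",
    "sidechain_contacts",
    "interaction_strength",
    "build_network",
    "imin_scan",
    "ensemble_network",
    "find_hubs",
]

# Residue-type normalization values N_i (maximal side-chain contact
# capacity per type) as used in the classical protein-structure-network
# construction of Kannan & Vishveshwara; overridable via PsnConfig.
DEFAULT_NORMALIZATION: dict[str, float] = {
    "ALA": 55.7551, "ARG": 93.7891, "ASN": 73.4097, "ASP": 75.1507,
    "CYS": 54.9528, "GLN": 78.1301, "GLU": 78.8288, "GLY": 47.3129,
    "HIS": 83.7357, "ILE": 67.9452, "LEU": 72.2517, "LYS": 69.6096,
    "MET": 69.2569, "PHE": 93.3082, "PRO": 51.3310, "SER": 61.3946,
    "THR": 63.7075, "TRP": 106.7030, "TYR": 100.7190, "VAL": 62.3673,
}


@dataclass
class PsnConfig:
    """Knobs of the network construction.

    ``normalization``: ``"table"`` (the packaged per-type values, merged
    with ``normalization_table`` overrides), ``"unit"`` (N_i = 1, so
    I_ij is just 100 n_ij) or ``"empirical"`` (N_i set per type to the
    maximum total contact count observed for that type in the input
    ensemble — useful for synthetic structures outside the 20 canonical
    types' contact regime).
    """

    cutoff: float = 4.5                 # atom-pair distance cutoff, A
    i_min: float = 3.0                  # interaction-strength cutoff, %
    occupancy_threshold: float = 0.75   # strict: stable iff occ > this
    hub_degree: int = 4
    n_snapshots: int = 500
    normalization: str = "table"
    normalization_table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.i_min < 0:
            raise ValueError("I_min must be non-negative")
        if not (0.0 < self.occupancy_threshold <= 1.0):
            raise ValueError("occupancy threshold must lie in (0, 1]")

    def table_for(self, res_names: list[str]) -> np.ndarray:
        if self.normalization == "unit":
            return np.ones(len(res_names))
        if self.normalization not in ("table", "empirical"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        table = {**DEFAULT_NORMALIZATION, **self.normalization_table}
        missing = sorted({r for r in res_names if r not in table})
        if missing:
            raise ValueError(
                f"no normalization value for residue type(s) {missing}"
            )
        values = np.array([table[r] for r in res_names], dtype=float)
        if np.any(values <= 0):
            bad = sorted({r for r, v in zip(res_names, values) if v <= 0})
            raise ValueError(f"nonpositive normalization for {bad}")
        return values


@dataclass
class ContactNetwork:
    """Residue graph with contact counts, strengths and occupancies.

    ``graph`` nodes are residue keys; edge attributes: ``n_ij`` (mean
    atom-pair count), ``I`` (mean strength, %), ``occupancy`` and
    ``stable``.  ``presence`` (optional) holds the per-snapshot boolean
    edge-presence tensor for community-stability analysis.
    """

    graph: nx.Graph
    residue_keys: list[ResidueKey]
    residue_names: list[str]
    config: PsnConfig
    presence: np.ndarray | None = None      # (n_snapshots, N, N) bool

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def adjacency(self) -> np.ndarray:
        index = {k: i for i, k in enumerate(self.residue_keys)}
        a = np.zeros((self.n_residues, self.n_residues), dtype=int)
        for u, v in self.graph.edges:
            a[index[u], index[v]] = a[index[v], index[u]] = 1
        return a

    def stable_network(self) -> "ContactNetwork":
        """Subnetwork of edges whose occupancy beats the threshold."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for u, v, data in self.graph.edges(data=True):
            if data.get("stable", True):
                g.add_edge(u, v, **data)
        return replace(self, graph=g)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            rows.append(
                {
                    "chain_i": u[0], "res_i": f"{u[1]}{u[2]}",
                    "chain_j": v[0], "res_j": f"{v[1]}{v[2]}",
                    "n_ij": data.get("n_ij", np.nan),
                    "I": data.get("I", np.nan),
                    "occupancy": data.get("occupancy", np.nan),
                    "stable": data.get("stable", True),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chain_i", "res_i", "chain_j", "res_j",
                "n_ij", "I", "occupancy", "stable",
            ],
        )


def _sequence_neighbor_matrix(keys: list[ResidueKey]) -> np.ndarray:
    """True where two residues are within one sequence position in the
    same chain (includes the diagonal)."""
    chains = np.array([k[0] for k in keys])
    pos = np.empty(len(keys), dtype=int)
    counters: dict[str, int] = {}
    for i, k in enumerate(keys):
        pos[i] = counters.get(k[0], 0)
        counters[k[0]] = pos[i] + 1
    same = chains[:, None] == chains[None, :]
    return same & (np.abs(pos[:, None] - pos[None, :]) <= 1)


def sidechain_contacts(
    coords: np.ndarray | Structure,
    selection: ResidueSelection,
    cutoff: float = 4.5,
) -> np.ndarray:
    """Side-chain heavy-atom pair counts n_ij for one frame.

    ``coords`` is either a Structure or a raw (n_atoms, 3) array over
    the selection's topology.  The count is symmetric and includes
    sequence-neighbour pairs (their exclusion is a network-construction
    rule, applied later, not a counting rule).
    """
    xyz = coords.coords if isinstance(coords, Structure) else np.asarray(coords)
    n_res = selection.n_residues
    counts = np.zeros((n_res, n_res), dtype=int)
    if cutoff <= 0:
        return counts
    flat = selection.flat_indices()
    atom_res = np.concatenate(
        [np.full(len(idx), r) for r, idx in enumerate(selection.atom_indices)]
    )
    pts = xyz[flat]
    tree = cKDTree(pts)
    for a, b in tree.query_pairs(r=cutoff):
        ra, rb = atom_res[a], atom_res[b]
        if ra != rb:
            counts[ra, rb] += 1
            counts[rb, ra] += 1
    return counts


def interaction_strength(
    n_ij: np.ndarray,
    selection: ResidueSelection,
    config: PsnConfig | None = None,
    norm_values: np.ndarray | None = None,
) -> np.ndarray:
    """Percent interaction strength I_ij = 100 n_ij / sqrt(N_i N_j)."""
    config = config or PsnConfig()
    if not np.array_equal(n_ij, n_ij.T):
        raise ValueError("contact count matrix must be symmetric")
    if norm_values is None:
        norm_values = config.table_for(list(selection.residue_names))
    if np.any(norm_values <= 0):
        raise ValueError("normalization values must be positive")
    strength = 100.0 * n_ij / np.sqrt(np.outer(norm_values, norm_values))
    np.fill_diagonal(strength, 0.0)
    return strength


def build_network(
    strength: np.ndarray,
    selection: ResidueSelection,
    config: PsnConfig | None = None,
    n_ij: np.ndarray | None = None,
) -> ContactNetwork:
    """Graph with an edge wherever I_ij strictly exceeds I_min.

    Sequence-neighbour pairs within a chain are never connected;
    inter-chain pairs are always eligible.
    """
    config = config or PsnConfig()
    if not np.allclose(strength, strength.T):
        raise ValueError("strength matrix must be symmetric")
    keys = selection.residue_keys
    neighbor = _sequence_neighbor_matrix(keys)
    g = nx.Graph()
    g.add_nodes_from(keys)
    idx_i, idx_j = np.where(
        np.triu(strength > config.i_min, k=1) & ~neighbor
    )
    for i, j in zip(idx_i, idx_j):
        attrs = {"I": float(strength[i, j])}
        if n_ij is not None:
            attrs["n_ij"] = float(n_ij[i, j])
        g.add_edge(keys[i], keys[j], **attrs)
    return ContactNetwork(
        graph=g, residue_keys=list(keys),
        residue_names=list(selection.residue_names), config=config,
    )


def imin_scan(
    strength: np.ndarray,
    selection: ResidueSelection,
    grid: list[float] | np.ndarray,
) -> pd.DataFrame:
    """Largest-connected-cluster size along an ascending I_min grid.

    The percolation transition estimate is the grid point with the
    largest drop in cluster size from its predecessor; a flat scan
    (fully connected throughout) leaves the transition flagged undefined
    (NaN in the ``transition`` column except at the estimated point).
    """
    grid = list(grid)
    if len(grid) < 2:
        raise ValueError("I_min grid needs at least 2 points")
    if sorted(grid) != grid:
        raise ValueError("I_min grid must be sorted ascending")
    sizes = []
    for i_min in grid:
        cfg = PsnConfig(i_min=float(i_min), normalization="unit")
        net = build_network(strength, selection, cfg)
        comps = list(nx.connected_components(net.graph))
        sizes.append(max((len(c) for c in comps), default=0))
    drops = [0] + [sizes[i - 1] - sizes[i] for i in range(1, len(sizes))]
    transition = grid[int(np.argmax(drops))] if max(drops) > 0 else np.nan
    return pd.DataFrame(
        {
            "i_min": grid,
            "largest_cluster": sizes,
            "drop": drops,
            "transition": [
                g == transition if not np.isnan(transition) else False
                for g in grid
            ],
        }
    )


def _snapshot_indices(n_frames: int, n_snapshots: int) -> np.ndarray:
    if n_frames <= n_snapshots:
        return np.arange(n_frames)
    return np.unique(
        np.round(np.linspace(0, n_frames - 1, n_snapshots)).astype(int)
    )


def ensemble_network(
    ensemble: ConformationalEnsemble,
    config: PsnConfig | None = None,
    selection: ResidueSelection | None = None,
) -> ContactNetwork:
    """Occupancy-annotated network over evenly spaced ensemble snapshots.

    Per snapshot an edge exists iff I_ij > I_min (and the pair is not a
    sequence-neighbour pair); occupancy is the fraction of snapshots
    with the edge present and an edge is dynamically stable iff its
    occupancy strictly exceeds the threshold.
    """
    config = config or PsnConfig()
    if ensemble.n_frames < 2:
        raise ValueError("ensemble network needs at least 2 frames")
    selection = selection or select_residue_atoms(ensemble, "sidechain")
    keys = selection.residue_keys
    snaps = _snapshot_indices(ensemble.n_frames, config.n_snapshots)
    n_res = selection.n_residues
    counts = np.zeros((len(snaps), n_res, n_res), dtype=int)
    for s, f in enumerate(snaps):
        counts[s] = sidechain_contacts(
            ensemble.frames[f], selection, config.cutoff
        )
    if config.normalization == "empirical":
        totals = counts.sum(axis=2)         # (snap, res): contacts per residue
        per_type: dict[str, float] = {}
        for r, name in enumerate(selection.residue_names):
            per_type[name] = max(per_type.get(name, 0.0), totals[:, r].max())
        norm_values = np.array(
            [max(per_type[name], 1.0) for name in selection.residue_names]
        )
    else:
        norm_values = config.table_for(list(selection.residue_names))

    neighbor = _sequence_neighbor_matrix(keys)
    presence = np.zeros((len(snaps), n_res, n_res), dtype=bool)
    strengths = np.zeros((len(snaps), n_res, n_res))
    for s in range(len(snaps)):
        strengths[s] = interaction_strength(
            counts[s], selection, config, norm_values=norm_values
        )
        presence[s] = (strengths[s] > config.i_min) & ~neighbor
    occupancy = presence.mean(axis=0)
    g = nx.Graph()
    g.add_nodes_from(keys)
    idx_i, idx_j = np.where(np.triu(occupancy > 0, k=1))
    for i, j in zip(idx_i, idx_j):
        g.add_edge(
            keys[i], keys[j],
            n_ij=float(counts[:, i, j].mean()),
            I=float(strengths[:, i, j].mean()),
            occupancy=float(occupancy[i, j]),
            stable=bool(occupancy[i, j] > config.occupancy_threshold),
        )
    return ContactNetwork(
        graph=g, residue_keys=list(keys),
        residue_names=list(selection.residue_names), config=config,
        presence=presence,
    )


def find_hubs(
    network: ContactNetwork, threshold: int | None = None
) -> list[tuple[ResidueKey, int]]:
    """Nodes with degree >= threshold, by descending degree then key."""
    threshold = network.config.hub_degree if threshold is None else threshold
    hubs = [
        (node, deg)
        for node, deg in network.graph.degree
        if deg >= threshold
    ]
    return sorted(hubs, key=lambda t: (-t[1], t[0]))
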