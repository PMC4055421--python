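"""Synthetic ensembles, structures and graphs with known ground truth.

Real inputs to this pipeline are MD ensembles; at test scale those are
replaced by generators whose statistical structure is known in closed
form, so every downstream stage has an analytic or brute-force oracle:

* Gaussian-network ensembles with a prescribed covariance (the scaled
  pseudo-inverse of a Kirchhoff matrix) for fluctuation, correlation and
  PCA oracles;
* rigid two-domain motion about a flexible hinge, emulating the
  quasi-rigid-domain phenomenology that makes hinge residues rigid
  (high force constant) and domain extremities mobile;
* a small all-atom structure whose side-chain contact counts are
  documented in a sidecar manifest;
* graphs with planted clique communities for percolation oracles.

All randomness in the package is confined to this module; generators are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .ensemble_io import ConformationalEnsemble, Structure

__all__ = [
    "GnmModel",
    "PlantedGraph",
    "build_toy_chain",
    "gnm_from_structure",
    "sample_gaussian_ensemble",
    "make_hinge_ensemble",
    "make_bridge_ensemble",
    "hinge_residue_groups",
    "brute_force_percolation",
    "make_contact_fixture",
    "write_contact_fixture",
    "make_planted_community_graph",
]


def _gly_chain_structure(coords: np.ndarray, chain_id: str = "A") -> Structure:
    """One-atom-per-residue chain; glycine so the CA doubles as the
    side-chain fallback in contact analysis."""
    n = len(coords)
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.full(n, "CA", dtype="U6"),
        res_name=np.full(n, "GLY", dtype="U5"),
        chain_id=np.full(n, chain_id, dtype="U4"),
        res_id=np.arange(1, n + 1),
        ins_code=np.full(n, "", dtype="U1"),
        element=np.full(n, "C", dtype="U2"),
        coords=np.asarray(coords, dtype=float),
    )


def _compact_cluster(
    n: int, center: np.ndarray, rng: np.random.Generator,
    min_sep: float = 3.4, radius: float | None = None,
) -> np.ndarray:
    """Random points in a ball around ``center`` with a minimum pairwise
    separation (rejection sampling; deterministic given the rng state)."""
    if radius is None:
        radius = max(4.0, 2.4 * n ** (1 / 3))
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 20000:
            radius *= 1.3
            attempts = 0
            pts = []
        p = center + rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p - center) > radius:
            continue
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return np.asarray(pts)


def build_toy_chain(
    n_res: int, geometry: str = "extended", seed: int = 0
) -> Structure:
    """Deterministic toy CA chain: ``extended``, ``helix`` or ``dumbbell``.

    The dumbbell places two compact clusters of ``n_res // 2`` residues
    joined by a short linker, giving inter-cluster centroid separation
    well beyond either cluster radius.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    if geometry == "extended":
        coords = np.zeros((n_res, 3))
        coords[:, 0] = 3.8 * np.arange(n_res)
    elif geometry == "helix":
        t = np.arange(n_res) * np.deg2rad(100.0)
        coords = np.column_stack(
            [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_res)]
        )
    elif geometry == "dumbbell":
        n_a = n_res // 2
        n_link = max(1, n_res - 2 * n_a) if n_res > 2 * n_a else 0
        n_b = n_res - n_a - n_link
        sep = 26.0
        a = _compact_cluster(n_a, np.array([-sep / 2, 0.0, 0.0]), rng)
        b = _compact_cluster(n_b, np.array([sep / 2, 0.0, 0.0]), rng)
        parts = [a]
        if n_link:
            xs = np.linspace(-sep / 2 + 5.0, sep / 2 - 5.0, n_link + 2)[1:-1]
            parts.append(np.column_stack([xs, np.zeros(n_link), np.zeros(n_link)]))
        parts.append(b)
        coords = np.vstack(parts)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return _gly_chain_structure(coords)


# ---------------------------------------------------------------------------
# Gaussian-network ensembles


@dataclass
class GnmModel:
    """Isotropic Gaussian fluctuation model over point residues.

    The per-node covariance (A^2, applied independently to each Cartesian
    axis) is the scaled pseudo-inverse of the Kirchhoff connectivity
    matrix, as in a Gaussian network model; ``scale`` plays the role of
    k_B T / gamma.
    """

    coords: np.ndarray          # (n, 3) mean structure, Angstrom
    cutoff: float               # spring cutoff, Angstrom
    scale: float = 1.0          # temperature scale, Angstrom^2
    kirchhoff: np.ndarray = field(init=False)
    covariance: np.ndarray = field(init=False)   # (n, n), per-axis, A^2

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        d = np.linalg.norm(
            self.coords[:, None, :] - self.coords[None, :, :], axis=-1
        )
        contact = (d <= self.cutoff) & ~np.eye(n, dtype=bool)
        k = -contact.astype(float)
        np.fill_diagonal(k, contact.sum(axis=1))
        self.kirchhoff = k
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        self.covariance = self.scale * np.linalg.pinv(k, hermitian=True)
        # guard: a disconnected model has >1 null mode and an ill-defined
        # fluctuation structure
        evals = np.linalg.eigvalsh(k)
        if np.sum(evals < 1e-9 * max(evals.max(), 1.0)) > 1:
            raise ValueError("Kirchhoff matrix is disconnected")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def correlation(self) -> np.ndarray:
        """Analytic residue cross-correlation implied by the covariance."""
        sig = np.sqrt(np.diag(self.covariance))
        c = self.covariance / np.outer(sig, sig)
        np.fill_diagonal(c, 1.0)
        return np.clip(c, -1.0, 1.0)

    def bfactors(self) -> np.ndarray:
        """Analytic B-factors: (8 pi^2 / 3) * 3 sigma_ii^2 per node."""
        return 8.0 * np.pi**2 * np.diag(self.covariance)


def gnm_from_structure(
    structure: Structure, cutoff: float = 7.5, scale: float = 1.0
) -> GnmModel:
    return GnmModel(coords=structure.coords.copy(), cutoff=cutoff, scale=scale)


def sample_gaussian_ensemble(
    model: GnmModel, n_frames: int, seed: int = 0
) -> tuple[ConformationalEnsemble, np.ndarray]:
    """Draw frames = mean + Gaussian displacements with the model covariance.

    Displacements on the three Cartesian axes are independent draws from
    N(0, covariance).  Returns the ensemble together with the exact
    per-axis covariance used, for oracle tests.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    cov = model.covariance
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals < -1e-8 * max(evals.max(), 1.0)):
        raise ValueError("covariance is not positive semidefinite")
    evals = np.clip(evals, 0.0, None)
    transform = evecs * np.sqrt(evals)          # (n, n), maps z -> Sigma^1/2 z
    rng = np.random.default_rng(seed)
    n = model.n_nodes
    z = rng.standard_normal(size=(n_frames, 3, n))
    disp = np.einsum("ij,fkj->fki", transform, z)   # (frames, 3, n)
    frames = model.coords[None, :, :] + np.transpose(disp, (0, 2, 1))
    topology = _gly_chain_structure(model.coords)
    ens = ConformationalEnsemble(topology=topology, frames=frames)
    return ens, cov.copy()


# ---------------------------------------------------------------------------
# Hinge ensembles


def _rotation_about_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_hinge_ensemble(
    n_per_domain: int = 20,
    hinge_len: int = 3,
    max_angle: float = 25.0,
    n_frames: int = 100,
    seed: int = 0,
    domain_sep: float = 24.0,
    hinge_offset: float = 0.5,
) -> ConformationalEnsemble:
    """Two internally rigid domains rotating about a hinge at the origin.

    Domain B is rotated about the z axis through the origin by an angle
    drawn uniformly in [-max_angle, +max_angle] degrees per frame; domain
    A and the hinge stay fixed.  Hinge residues sit ``hinge_offset`` A
    off the rotation axis, so their mean distance to the rest of the
    protein fluctuates only marginally — they are the rigid, high
    force-constant sites by construction, while domain extremities sweep
    large distance changes.
    """
    if not (0.0 < max_angle < 180.0):
        raise ValueError("max_angle must lie in (0, 180) degrees")
    if hinge_len < 1:
        raise ValueError("hinge_len must be at least 1")
    if n_per_domain < 3:
        raise ValueError("need at least 3 residues per domain")
    rng = np.random.default_rng(seed)
    a = _compact_cluster(
        n_per_domain, np.array([-domain_sep / 2, 0.0, 0.0]), rng
    )
    b = _compact_cluster(
        n_per_domain, np.array([domain_sep / 2, 0.0, 0.0]), rng
    )
    hinge = np.column_stack(
        [
            np.zeros(hinge_len),
            np.full(hinge_len, hinge_offset),
            1.8 * (np.arange(hinge_len) - (hinge_len - 1) / 2),
        ]
    )
    base = np.vstack([a, hinge, b])
    b_slice = slice(n_per_domain + hinge_len, None)

    angles = rng.uniform(
        -np.deg2rad(max_angle), np.deg2rad(max_angle), size=n_frames
    )
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    for f, theta in enumerate(angles):
        frames[f, b_slice] = base[b_slice] @ _rotation_about_z(theta).T
    topology = _gly_chain_structure(base)
    return ConformationalEnsemble(topology=topology, frames=frames)


def make_bridge_ensemble(
    n_frames: int = 200,
    seed: int = 0,
    mode_amplitude: float = 0.35,
    noise: float = 0.08,
) -> tuple[ConformationalEnsemble, dict[str, list[int]]]:
    """Two dense residue clusters joined by a single bridge residue.

    Each cluster is an octahedron of six residues whose adjacent
    vertices sit within contact range of each other; the bridge at the
    origin touches exactly one inner vertex of each cluster and is the
    only route between them, so it is the betweenness maximum of the
    contact network by construction.  Frames superimpose an asymmetric
    stretching mode (amplitudes -1 on cluster A, +0.5 on the bridge,
    +1 on cluster B, along x) on i.i.d. atomic noise: after removal of
    the overall fit the mode survives as strong inter-residue
    correlation, while occasional noise excursions drop marginal
    intra-cluster contacts in a minority of frames — exercising the
    occupancy filter without breaking the planted topology.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    # octahedron rotated 45 deg about z: two "inner" equatorial vertices
    # face the bridge, so each cluster offers two entry contacts and the
    # bridge alone lies on every cross-cluster path
    q = 3.0 / np.sqrt(2.0)
    octa = np.array(
        [
            [q, q, 0.0], [q, -q, 0.0],        # inner pair (toward bridge)
            [0.0, 0.0, 3.0], [0.0, 0.0, -3.0],
            [-q, q, 0.0], [-q, -q, 0.0],      # outer pair
        ]
    )
    center_a, center_b = np.array([-5.0, 0, 0]), np.array([5.0, 0, 0])
    cluster_a = octa + center_a               # ids 1..6; ids 1,2 inner
    cluster_b = octa * [-1, 1, 1] + center_b  # mirrored
    bridge = np.zeros((1, 3))
    # order B so its outer vertices get ids 8,9 (the bridge's sequence
    # neighbour id 8 can then never be a contact partner) and the inner
    # pair ids 12,13
    coords = np.vstack([cluster_a, bridge, cluster_b[::-1]])
    groups = {
        "cluster_a": list(range(1, 7)),
        "bridge": [7],
        "cluster_b": list(range(8, 14)),
    }
    alpha = np.array([-1.0] * 6 + [0.5] + [1.0] * 6)
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, mode_amplitude, size=n_frames)
    eps = rng.normal(0.0, noise, size=(n_frames, len(coords), 3))
    frames = coords[None, :, :] + eps
    frames[:, :, 0] += s[:, None] * alpha[None, :]
    topology = _gly_chain_structure(coords)
    return ConformationalEnsemble(topology=topology, frames=frames), groups


def hinge_residue_groups(
    n_per_domain: int, hinge_len: int
) -> dict[str, list[int]]:
    """Residue ids (1-based) of the three segments of a hinge ensemble."""
    a = list(range(1, n_per_domain + 1))
    h = list(range(n_per_domain + 1, n_per_domain + hinge_len + 1))
    b = list(
        range(n_per_domain + hinge_len + 1, 2 * n_per_domain + hinge_len + 1)
    )
    return {"domain_a": a, "hinge": h, "domain_b": b}


# ---------------------------------------------------------------------------
# All-atom contact fixture


def _fixture_atoms() -> list[tuple[int, str, str, np.ndarray]]:
    """(res_id, res_name, atom_name, coord) for the contact fixture.

    Side-chain placements are engineered so that specific residue pairs
    have small, hand-countable numbers of heavy-atom pairs within 4.5 A;
    backbones sit on a parallel line 8 A away and never contribute.
    """
    atoms: list[tuple[int, str, str, np.ndarray]] = []

    def backbone(res_id: int, res_name: str) -> None:
        x = 3.0 * res_id
        atoms.append((res_id, res_name, "N", np.array([x, -8.0, 0.0])))
        atoms.append((res_id, res_name, "CA", np.array([x, -7.0, 0.0])))
        atoms.append((res_id, res_name, "C", np.array([x, -6.0, 0.0])))
        atoms.append((res_id, res_name, "O", np.array([x, -6.0, 1.2])))

    backbone(1, "SER")
    atoms.append((1, "SER", "CB", np.array([0.0, 0.0, 0.0])))
    atoms.append((1, "SER", "OG", np.array([0.0, 0.0, 1.4])))
    backbone(2, "ALA")
    atoms.append((2, "ALA", "CB", np.array([0.0, 3.0, 0.0])))
    backbone(3, "CYS")
    atoms.append((3, "CYS", "CB", np.array([4.0, 0.0, 0.0])))
    atoms.append((3, "CYS", "SG", np.array([4.0, 0.0, -1.8])))
    backbone(4, "VAL")
    atoms.append((4, "VAL", "CB", np.array([20.0, 0.0, 0.0])))
    atoms.append((4, "VAL", "CG1", np.array([20.0, 1.5, 0.0])))
    atoms.append((4, "VAL", "CG2", np.array([20.0, -1.5, 0.0])))
    backbone(5, "THR")
    atoms.append((5, "THR", "CB", np.array([8.0, 0.0, 0.0])))
    atoms.append((5, "THR", "OG1", np.array([8.0, 1.4, 0.0])))
    atoms.append((5, "THR", "CG2", np.array([8.0, -1.4, 0.0])))
    backbone(6, "LEU")
    atoms.append((6, "LEU", "CB", np.array([24.4, 0.0, 0.0])))
    atoms.append((6, "LEU", "CG", np.array([24.4, 0.0, 2.0])))
    atoms.append((6, "LEU", "CD1", np.array([24.4, 1.5, 3.0])))
    return atoms


def make_contact_fixture(cutoff: float = 4.5) -> tuple[Structure, dict]:
    """Deterministic 6-residue all-atom toy plus its contact manifest.

    The manifest's pairwise side-chain contact counts are produced here
    by a naive double loop over atoms, independent of the optimized
    contact counter they serve as an oracle for.  Sequence-neighbor
    pairs are listed but flagged excluded from the network.
    """
    atoms = _fixture_atoms()
    n = len(atoms)
    structure = Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.array([a[2] for a in atoms], dtype="U6"),
        res_name=np.array([a[1] for a in atoms], dtype="U5"),
        chain_id=np.full(n, "A", dtype="U4"),
        res_id=np.array([a[0] for a in atoms], dtype=int),
        ins_code=np.full(n, "", dtype="U1"),
        element=np.array([a[2][0] for a in atoms], dtype="U2"),
        coords=np.array([a[3] for a in atoms]),
    )

    # brute-force side-chain heavy-atom pair count within the cutoff
    backbone = {"N", "CA", "C", "O", "OXT"}
    res_ids = sorted({a[0] for a in atoms})
    res_names = {a[0]: a[1] for a in atoms}
    counts: dict[tuple[int, int], int] = {}
    for i_pos, i in enumerate(res_ids):
        for j in res_ids[i_pos + 1:]:
            c = 0
            for ri, rn_i, an_i, xi in atoms:
                if ri != i or an_i in backbone:
                    continue
                for rj, rn_j, an_j, xj in atoms:
                    if rj != j or an_j in backbone:
                        continue
                    if np.linalg.norm(xi - xj) <= cutoff:
                        c += 1
            if c:
                counts[(i, j)] = c
    manifest = {
        "cutoff": cutoff,
        "chain": "A",
        "res_names": {str(k): v for k, v in res_names.items()},
        "contacts": [
            {
                "res_i": i,
                "res_j": j,
                "n_ij": c,
                "sequence_neighbors": abs(i - j) <= 1,
            }
            for (i, j), c in sorted(counts.items())
        ],
    }
    return structure, manifest


def write_contact_fixture(directory: str | Path, cutoff: float = 4.5) -> dict:
    """Emit the contact fixture as PDB + JSON manifest; returns the manifest."""
    from .ensemble_io import write_multimodel_pdb

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    structure, manifest = make_contact_fixture(cutoff)
    ens = ConformationalEnsemble(
        topology=structure, frames=structure.coords[None, :, :]
    )
    write_multimodel_pdb(ens, directory / "contact_fixture.pdb")
    with open(directory / "contact_fixture.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# Planted clique communities


@dataclass
class PlantedGraph:
    """Chain of complete subgraphs with recorded memberships."""

    graph: nx.Graph
    cliques: list[frozenset]

    def expected_communities(self, k: int, min_shared: int) -> list[frozenset]:
        """Ground-truth communities by union-find over the planted
        cliques of size >= k (each contributes its size-k subcliques;
        since planted cliques are complete, adjacency reduces to overlap
        of the planted cliques themselves for overlap >= min_shared)."""
        from itertools import combinations

        k_cliques = sorted(
            {
                frozenset(sub)
                for cl in self.cliques
                if len(cl) >= k
                for sub in combinations(sorted(cl), k)
            }
        )
        return brute_force_percolation(k_cliques, min_shared)


def brute_force_percolation(
    cliques: list[frozenset], min_shared: int
) -> list[frozenset]:
    """Reference percolation: BFS over the clique-adjacency graph."""
    n = len(cliques)
    seen = [False] * n
    communities: list[frozenset] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, members = [start], set()
        seen[start] = True
        while stack:
            cur = stack.pop()
            members |= cliques[cur]
            for other in range(n):
                if not seen[other] and len(cliques[cur] & cliques[other]) >= min_shared:
                    seen[other] = True
                    stack.append(other)
        communities.append(frozenset(members))
    return sorted(communities, key=lambda c: (sorted(c), len(c)))


def make_planted_community_graph(
    clique_sizes: list[int], shared_nodes: int, seed: int = 0
) -> PlantedGraph:
    """Chain of complete subgraphs, consecutive pairs sharing exactly
    ``shared_nodes`` nodes; node labels are shuffled by the seed."""
    if any(s < 3 for s in clique_sizes):
        raise ValueError("clique sizes must all be >= 3")
    if clique_sizes and shared_nodes >= min(clique_sizes):
        raise ValueError("shared_nodes must be smaller than every clique")
    if shared_nodes < 0:
        raise ValueError("shared_nodes must be non-negative")
    cliques: list[list[int]] = []
    next_node = 0
    prev: list[int] = []
    for size in clique_sizes:
        shared = prev[-shared_nodes:] if shared_nodes and prev else []
        fresh = list(range(next_node, next_node + size - len(shared)))
        next_node += len(fresh)
        clique = shared + fresh
        cliques.append(clique)
        prev = clique
    rng = np.random.default_rng(seed)
    relabel = dict(zip(range(next_node), rng.permutation(next_node).tolist()))
    graph = nx.Graph()
    graph.add_nodes_from(range(next_node))
    mapped = []
    for clique in cliques:
        nodes = [relabel[v] for v in clique]
        mapped.append(frozenset(nodes))
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                graph.add_edge(u, v)
    return PlantedGraph(graph=graph, cliques=mapped)
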