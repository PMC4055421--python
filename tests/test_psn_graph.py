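import numpy as np
import pytest

from conftest import gly_ensemble
from psnflow.ensemble_io import select_residue_atoms
from psnflow.psn_graph import (
    DEFAULT_NORMALIZATION,
    PsnConfig,
    build_network,
    ensemble_network,
    find_hubs,
    imin_scan,
    interaction_strength,
    sidechain_contacts,
)
from psnflow.synthetic_data import make_contact_fixture


@pytest.fixture
def fixture_net(contact_fixture):
    structure, manifest = contact_fixture
    sel = select_residue_atoms(structure, "sidechain")
    counts = sidechain_contacts(structure, sel, cutoff=manifest["cutoff"])
    return structure, manifest, sel, counts


class TestContacts:
    def test_counts_reproduce_the_manifest(self, fixture_net):
        _, manifest, sel, counts = fixture_net
        documented = {
            (c["res_i"], c["res_j"]): c["n_ij"] for c in manifest["contacts"]
        }
        n = sel.n_residues
        for i in range(n):
            for j in range(i + 1, n):
                expected = documented.get((i + 1, j + 1), 0)
                assert counts[i, j] == expected, (i + 1, j + 1)
        np.testing.assert_array_equal(counts, counts.T)

    def test_zero_cutoff_gives_no_contacts(self, fixture_net):
        structure, _, sel, _ = fixture_net
        assert sidechain_contacts(structure, sel, cutoff=0.0).sum() == 0

    def test_far_apart_structure_gives_no_contacts(self):
        coords = np.arange(5)[:, None] * [20.0, 0.0, 0.0]
        ens = gly_ensemble(coords[None])
        sel = select_residue_atoms(ens, "sidechain")
        assert sidechain_contacts(ens.frames[0], sel, 4.5).sum() == 0


class TestInteractionStrength:
    def test_direct_formula_value(self):
        # n=5, N_i=100, N_j=64 -> 100*5/80 = 6.25 %
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 30.0
        ens = gly_ensemble(coords)
        sel = select_residue_atoms(ens, "sidechain")
        n_ij = np.array([[0, 5], [5, 0]])
        strength = interaction_strength(
            n_ij, sel, PsnConfig(), norm_values=np.array([100.0, 64.0])
        )
        assert strength[0, 1] == pytest.approx(6.25, abs=1e-12)
        assert strength[1, 0] == strength[0, 1]
        assert strength[0, 0] == 0.0

    def test_scale_equivariance_in_counts(self, fixture_net):
        _, _, sel, counts = fixture_net
        cfg = PsnConfig()
        s1 = interaction_strength(counts, sel, cfg)
        s2 = interaction_strength(2 * counts, sel, cfg)
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_missing_residue_type_is_an_error(self):
        coords = np.zeros((1, 2, 3))
        ens = gly_ensemble(coords)
        ens.topology.res_name[:] = "XYZ"
        sel = select_residue_atoms(ens, "sidechain")
        with pytest.raises(ValueError, match="XYZ"):
            interaction_strength(np.zeros((2, 2), dtype=int), sel, PsnConfig())


class TestNetworkConstruction:
    def test_fixture_edges_at_default_cutoff(self, fixture_net):
        structure, manifest, sel, counts = fixture_net
        cfg = PsnConfig()      # I_min = 3 %, packaged table
        strength = interaction_strength(counts, sel, cfg)
        net = build_network(strength, sel, cfg, n_ij=counts)
        edges = {
            tuple(sorted((u[1], v[1]))) for u, v in net.graph.edges
        }
        # manifest pairs whose strength beats 3 % and are not neighbours
        table = DEFAULT_NORMALIZATION
        names = manifest["res_names"]
        expected = set()
        for c in manifest["contacts"]:
            if c["sequence_neighbors"]:
                continue
            i, j = c["res_i"], c["res_j"]
            s = 100.0 * c["n_ij"] / np.sqrt(
                table[names[str(i)]] * table[names[str(j)]]
            )
            if s > cfg.i_min:
                expected.add((i, j))
        assert edges == expected
        assert (1, 3) in edges and (3, 5) in edges
        assert (1, 2) not in edges          # neighbours stay unconnected
        assert (4, 6) not in edges          # 1 contact is below 3 %

    def test_boundary_is_strict(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 1, 1] = 30.0
        coords[0, 2, 0] = 60.0
        ens = gly_ensemble(coords)
        sel = select_residue_atoms(ens, "sidechain")
        strength = np.zeros((3, 3))
        strength[0, 2] = strength[2, 0] = 3.0
        cfg = PsnConfig(i_min=3.0, normalization="unit")
        assert build_network(strength, sel, cfg).graph.number_of_edges() == 0
        strength[0, 2] = strength[2, 0] = 3.0001
        assert build_network(strength, sel, cfg).graph.number_of_edges() == 1

    def test_edge_sets_nest_along_imin_grid(self, fixture_net):
        _, _, sel, counts = fixture_net
        cfg = PsnConfig()
        strength = interaction_strength(counts, sel, cfg)
        prev = None
        for i_min in [0.5, 1.0, 2.0, 3.0, 5.0, 8.0]:
            net = build_network(
                strength, sel, PsnConfig(i_min=i_min)
            )
            edges = set(map(tuple, map(sorted, net.graph.edges)))
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestIminScan:
    def test_uniform_strengths_collapse_at_their_value(self):
        coords = np.arange(6)[:, None] * [10.0, 0.0, 0.0]
        ens = gly_ensemble(coords[None])
        sel = select_residue_atoms(ens, "sidechain")
        strength = np.full((6, 6), 5.0)
        np.fill_diagonal(strength, 0.0)
        scan = imin_scan(strength, sel, [4.0, 4.9, 5.1, 6.0])
        sizes = scan["largest_cluster"].tolist()
        assert sizes[0] == 6 and sizes[1] == 6
        assert sizes[2] == 1
        assert scan.loc[scan["transition"], "i_min"].tolist() == [5.1]

    def test_cluster_size_never_increases(self, fixture_net):
        _, _, sel, counts = fixture_net
        strength = interaction_strength(counts, sel, PsnConfig())
        scan = imin_scan(strength, sel, list(np.linspace(0.5, 9, 12)))
        sizes = scan["largest_cluster"].to_numpy()
        assert np.all(np.diff(sizes) <= 0)

    def test_short_grid_rejected(self, fixture_net):
        _, _, sel, counts = fixture_net
        strength = interaction_strength(counts, sel, PsnConfig())
        with pytest.raises(ValueError):
            imin_scan(strength, sel, [3.0])


class TestEnsembleOccupancy:
    def _toggle_ensemble(self, n_present: int, n_total: int = 10):
        """Residues 1 and 3 in contact in n_present of n_total frames."""
        frames = np.zeros((n_total, 3, 3))
        frames[:, 1, 1] = 30.0               # residue 2 parked far away
        frames[:, 2, 0] = 3.0                # contact position
        frames[n_present:, 2, 0] = 20.0      # broken position
        return gly_ensemble(frames)

    def test_strict_threshold_keeps_08_drops_07(self):
        cfg = PsnConfig(normalization="unit", i_min=3.0)
        net8 = ensemble_network(self._toggle_ensemble(8), cfg)
        edge8 = net8.graph.edges[("A", 1, ""), ("A", 3, "")]
        assert edge8["occupancy"] == pytest.approx(0.8)
        assert edge8["stable"]
        net7 = ensemble_network(self._toggle_ensemble(7), cfg)
        edge7 = net7.graph.edges[("A", 1, ""), ("A", 3, "")]
        assert edge7["occupancy"] == pytest.approx(0.7)
        assert not edge7["stable"]
        assert net7.stable_network().graph.number_of_edges() == 0

    def test_rigid_ensemble_occupancy_is_binary(self):
        base = np.random.default_rng(4).normal(size=(8, 3)) * 4
        ens = gly_ensemble(np.repeat(base[None], 6, axis=0))
        cfg = PsnConfig(normalization="unit")
        net = ensemble_network(ens, cfg)
        occ = [d["occupancy"] for *_, d in net.graph.edges(data=True)]
        assert set(occ) <= {0.0, 1.0}

    def test_snapshot_subsampling_is_deterministic(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(40, 6, 3)) * 2
        ens = gly_ensemble(frames)
        cfg = PsnConfig(normalization="unit", n_snapshots=10)
        a = ensemble_network(ens, cfg)
        b = ensemble_network(ens, cfg)
        assert a.edge_table().equals(b.edge_table())
        assert a.presence.shape[0] == 10


class TestHubs:
    def test_star_center_is_a_hub_at_threshold_four(self):
        # center residue 1 within contact range of residues 3..6
        coords = np.zeros((7, 3))
        coords[1] = [40.0, 0, 0]     # residue 2 far (sequence neighbour)
        directions = np.array(
            [[3.5, 0, 0], [-3.5, 0, 0], [0, 3.5, 0], [0, -3.5, 0], [0, 0, 3.5]]
        )
        coords[2:7] = directions
        ens = gly_ensemble(coords[None])
        sel = select_residue_atoms(ens, "sidechain")
        counts = sidechain_contacts(ens.frames[0], sel, 4.5)
        strength = interaction_strength(
            counts, sel, PsnConfig(normalization="unit")
        )
        net = build_network(strength, sel, PsnConfig(normalization="unit"))
        hubs = find_hubs(net, threshold=4)
        degrees = dict(net.graph.degree)
        center = ("A", 1, "")
        assert degrees[center] >= 4
        assert center in [h for h, _ in hubs]
        # degree-3 nodes are not hubs
        assert all(d >= 4 for _, d in hubs)

    def test_empty_network_has_no_hubs(self):
        coords = np.arange(4)[:, None] * [25.0, 0.0, 0.0]
        ens = gly_ensemble(coords[None])
        sel = select_residue_atoms(ens, "sidechain")
        net = build_network(
            np.zeros((4, 4)), sel, PsnConfig(normalization="unit")
        )
        assert find_hubs(net) == []

    def test_degree_matches_adjacency_row_sums(self, fixture_net):
        _, _, sel, counts = fixture_net
        strength = interaction_strength(counts, sel, PsnConfig())
        net = build_network(strength, sel, PsnConfig())
        a = net.adjacency()
        degrees = dict(net.graph.degree)
        for i, key in enumerate(net.residue_keys):
            assert degrees[key] == a[i].sum()
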