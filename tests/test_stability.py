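import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import gly_ensemble
from oracles import naive_force_constants
from psnflow.ensemble_io import select_residue_atoms
from psnflow.stability import (
    StabilityConfig,
    bfactors,
    differential_depth,
    force_constants,
    mean_distance_series,
    residue_depth_profile,
)
from psnflow.synthetic_data import make_hinge_ensemble, hinge_residue_groups


def _series(ens, **cfg_kwargs):
    cfg = StabilityConfig(**cfg_kwargs)
    sel = select_residue_atoms(ens, cfg_kwargs.get("mode", "calpha"))
    return mean_distance_series(ens, sel, cfg), cfg


class TestMeanDistanceSeries:
    def test_two_point_residues_give_their_separation(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 1, 0] = 5.0
        series, _ = _series(gly_ensemble(frames), exclusion_width=0)
        np.testing.assert_allclose(series.series, 5.0)

    def test_exclusion_window_starves_middle_residue(self):
        frames = np.zeros((2, 3, 3))
        frames[:, 1, 0], frames[:, 2, 0] = 4.0, 8.0
        with pytest.raises(ValueError, match=r"\('A', 2, ''\)"):
            _series(gly_ensemble(frames), exclusion_width=1)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            _series(gly_ensemble(np.zeros((1, 4, 3))))


class TestForceConstants:
    def test_matches_direct_formula_on_constructed_variance(self):
        # d(t) alternates 10 +/- sqrt(0.1): Var = 0.1 A^2 exactly, so
        # k = 3 * 1.9872e-3 * 300 / 0.1 = 17.885 kcal/mol/A^2
        rng = np.random.default_rng(0)
        n_frames = 6
        frames = np.zeros((n_frames, 2, 3))
        delta = np.sqrt(0.1)
        frames[:, 1, 0] = 10.0 + delta * np.array([1, -1, 1, -1, 1, -1])
        series, cfg = _series(gly_ensemble(frames), exclusion_width=0)
        prof = force_constants(series, cfg)
        expected = 3.0 * 1.987204259e-3 * 300.0 / 0.1
        np.testing.assert_allclose(prof.k, expected, rtol=1e-10)
        assert abs(expected - 17.885) < 1e-2

    def test_identical_frames_flagged_rigid(self):
        frames = np.repeat(
            np.random.default_rng(1).normal(size=(1, 5, 3)) * 10, 4, axis=0
        )
        series, cfg = _series(gly_ensemble(frames), exclusion_width=0)
        prof = force_constants(series, cfg)
        assert prof.rigid.all()
        assert np.isnan(prof.k).all()

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(scale=0.4, size=(60, 12, 3))
        frames += np.linspace(0, 40, 12)[None, :, None] * [1, 0, 0]
        ens = gly_ensemble(frames)
        series, cfg = _series(ens, exclusion_width=1)
        prof = force_constants(series, cfg)
        oracle = naive_force_constants(
            frames,
            chain_pos=np.arange(12),
            chains=np.zeros(12),
            exclusion_width=1,
        )
        np.testing.assert_allclose(prof.k, oracle, rtol=1e-10)

    def test_monotone_decreasing_in_variance(self):
        # larger fluctuation amplitude must give smaller k
        ks = []
        for amp in (0.1, 0.2, 0.4):
            frames = np.zeros((50, 2, 3))
            t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
            frames[:, 1, 0] = 10.0 + amp * np.sin(t)
            series, cfg = _series(gly_ensemble(frames), exclusion_width=0)
            ks.append(force_constants(series, cfg).k[0])
        assert ks[0] > ks[1] > ks[2]

    def test_invariant_under_global_rigid_transform(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(scale=0.3, size=(30, 8, 3))
        frames += np.linspace(0, 28, 8)[None, :, None] * [1, 0, 0]
        ens = gly_ensemble(frames)
        series, cfg = _series(ens)
        base = force_constants(series, cfg).k
        moved = frames.copy()
        for f in range(len(moved)):
            rot = Rotation.random(random_state=100 + f).as_matrix()
            moved[f] = moved[f] @ rot.T + rng.normal(scale=50.0, size=3)
        series2, _ = _series(gly_ensemble(moved))
        np.testing.assert_allclose(
            force_constants(series2, cfg).k, base, rtol=1e-9
        )

    def test_hinge_residues_outscore_distal_domains(self):
        n_dom, hlen = 12, 3
        ens = make_hinge_ensemble(n_dom, hlen, 25.0, 150, seed=4)
        series, cfg = _series(ens)
        prof = force_constants(series, cfg)
        groups = hinge_residue_groups(n_dom, hlen)
        hinge_k = prof.k[[i - 1 for i in groups["hinge"]]]
        distal_k = prof.k[
            [i - 1 for i in groups["domain_a"] + groups["domain_b"]]
        ]
        assert hinge_k.min() > np.median(distal_k)


class TestBfactors:
    def test_isotropic_gaussian_node_matches_closed_form(self):
        # per-axis variance 0.25 A^2 -> B = 8 pi^2 * 0.25
        rng = np.random.default_rng(8)
        frames = np.zeros((40_000, 2, 3))
        frames[:, 1, 0] = 20.0
        frames += rng.normal(scale=0.5, size=frames.shape)
        ens = gly_ensemble(frames)
        sel = select_residue_atoms(ens, "calpha")
        b = bfactors(ens, sel)["bfactor"].to_numpy()
        np.testing.assert_allclose(b, 8 * np.pi**2 * 0.25, rtol=0.05)

    def test_rigid_ensemble_is_zero_and_scaling_is_quadratic(self):
        base = np.random.default_rng(9).normal(size=(5, 3)) * 8
        rigid = gly_ensemble(np.repeat(base[None], 6, axis=0))
        sel = select_residue_atoms(rigid, "calpha")
        assert np.allclose(bfactors(rigid, sel)["bfactor"], 0.0)
        disp = np.random.default_rng(10).normal(size=(6, 5, 3)) * 0.3
        ens1 = gly_ensemble(base[None] + disp)
        ens2 = gly_ensemble(base[None] + 2 * disp)
        b1 = bfactors(ens1, sel)["bfactor"].to_numpy()
        b2 = bfactors(ens2, sel)["bfactor"].to_numpy()
        np.testing.assert_allclose(b2, 4 * b1, rtol=1e-10)


class TestResidueDepth:
    def test_isolated_atom_depth_is_radius_plus_probe(self):
        # two far-apart carbons: each one's nearest surface is its own
        # SAS sphere at vdW + probe = 1.7 + 1.4
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        ens = gly_ensemble(coords[None])
        prof = residue_depth_profile(ens, probe_radius=1.4, n_sphere_points=128)
        np.testing.assert_allclose(prof.depth, 3.1, atol=0.01)

    def test_cluster_core_is_deeper_than_periphery(self):
        # central atom fully enclosed by a dense spherical shell
        from psnflow.stability import _fibonacci_sphere

        shell = 3.5 * _fibonacci_sphere(30)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        ens = gly_ensemble(coords[None])
        prof = residue_depth_profile(ens, n_sphere_points=196)
        assert prof.depth[0] > prof.depth[1:].max()

    def test_point_density_convergence(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(scale=3.0, size=(12, 3))
        ens = gly_ensemble(coords[None])
        a = residue_depth_profile(ens, n_sphere_points=128).depth
        b = residue_depth_profile(ens, n_sphere_points=256).depth
        assert np.abs(a - b).max() < 0.1

    def test_differential_depth_antisymmetry_and_peak(self):
        from psnflow.stability import _fibonacci_sphere

        shell = 3.5 * _fibonacci_sphere(30)
        buried = np.vstack([[0.0, 0.0, 0.0], shell])
        exposed = buried.copy()
        exposed[0] = [15.0, 0.0, 0.0]     # residue 1 pulled out of the core
        prof_a = residue_depth_profile(gly_ensemble(buried[None]))
        prof_b = residue_depth_profile(gly_ensemble(exposed[None]))
        diff = differential_depth(prof_a, prof_b)
        flipped = differential_depth(prof_b, prof_a)
        np.testing.assert_allclose(
            diff["delta_depth"], -flipped["delta_depth"], atol=1e-12
        )
        assert diff["delta_depth"].idxmax() == 0
        assert diff["delta_depth"].iloc[0] > 1.0
        same = differential_depth(prof_a, prof_a)
        assert np.allclose(same["delta_depth"], 0.0)
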