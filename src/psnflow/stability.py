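"""Structural-stability profiling of conformational ensembles.

The central quantity is the per-residue effective force constant

    k_i = 3 k_B T / Var(d_i),

where d_i(t) is the mean distance between residue i and the rest of the
protein in frame t: stiff (structurally rigid) residues barely change
their mean distance to everything else over the ensemble, so their
variance is small and k_i large.  Hinge and inter-domain residues in
multi-domain proteins show up as force-constant peaks.  The module also
computes ensemble B-factors and sphere-point residue-depth profiles used
for differential solvent-protection comparisons between states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble_io import (
    ConformationalEnsemble,
    ResidueKey,
    ResidueSelection,
    profile_frame,
)

__all__ = [
    "StabilityConfig",
    "DistanceSeries",
    "ForceConstantProfile",
    "DepthProfile",
    "mean_distance_series",
    "force_constants",
    "bfactors",
    "residue_depth_profile",
    "differential_depth",
]

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 1.987204259e-3


@dataclass
class StabilityConfig:
    """Parameters of the force-constant calculation.

    ``constant_factor`` is the proportionality constant relating thermal
    energy to the distance-fluctuation variance; the default 3 follows
    the three Cartesian degrees of freedom of the fluctuation method,
    and 1-k_B-T variants are a parameter change, not a code change.
    ``exclusion_width`` w removes residues i-w..i+w (same chain) from
    residue i's distance average, because distances to covalent
    neighbours are nearly constant and would bias the variance down.
    """

    boltzmann: float = KB_KCAL
    temperature: float = 300.0
    constant_factor: float = 3.0
    exclusion_width: int = 1
    mode: str = "calpha"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.exclusion_width < 0:
            raise ValueError("exclusion width must be >= 0")


@dataclass
class DistanceSeries:
    """Per-frame mean distances d(t) for every selected atom.

    ``series`` has shape (n_frames, n_selected_atoms); ``atom_groups``
    maps each residue to its positions in the selected-atom axis.
    """

    series: np.ndarray
    residue_keys: list[ResidueKey]
    residue_names: list[str]
    atom_groups: list[np.ndarray]

    @property
    def n_frames(self) -> int:
        return self.series.shape[0]


@dataclass
class ForceConstantProfile:
    residue_keys: list[ResidueKey]
    residue_names: list[str]
    k: np.ndarray               # kcal mol^-1 A^-2; NaN where rigid
    mean_distance: np.ndarray   # A
    variance: np.ndarray        # A^2
    rigid: np.ndarray           # bool: zero-variance residues

    def to_frame(self) -> pd.DataFrame:
        sel = ResidueSelection(
            mode="profile",
            residue_keys=self.residue_keys,
            atom_indices=[np.array([0])] * len(self.residue_keys),
            residue_names=self.residue_names,
        )
        return profile_frame(
            sel, self.k, value_name="force_constant",
            mean_distance=self.mean_distance, variance=self.variance,
            rigid=self.rigid,
        )


@dataclass
class DepthProfile:
    residue_keys: list[ResidueKey]
    residue_names: list[str]
    depth: np.ndarray           # A below the solvent-accessible surface

    def as_dict(self) -> dict[ResidueKey, float]:
        return dict(zip(self.residue_keys, self.depth))


def _chain_positions(keys: list[ResidueKey]) -> np.ndarray:
    """Sequential position of each residue within its chain."""
    pos = np.empty(len(keys), dtype=int)
    counters: dict[str, int] = {}
    for idx, key in enumerate(keys):
        c = key[0]
        pos[idx] = counters.get(c, 0)
        counters[c] = pos[idx] + 1
    return pos


def _admissible_matrix(
    keys: list[ResidueKey], width: int
) -> np.ndarray:
    """admissible[i, j]: residue j's atoms enter residue i's average."""
    n = len(keys)
    chains = np.array([k[0] for k in keys])
    pos = _chain_positions(keys)
    same_chain = chains[:, None] == chains[None, :]
    close = np.abs(pos[:, None] - pos[None, :]) <= width
    return ~(same_chain & close)


def mean_distance_series(
    ensemble: ConformationalEnsemble,
    selection: ResidueSelection,
    config: StabilityConfig | None = None,
    chunk_frames: int = 512,
) -> DistanceSeries:
    """Mean distance from each selected atom to all admissible atoms.

    Admissible partners of an atom of residue i are the selection atoms
    of residues outside i's exclusion window (sequence neighbours within
    the same chain are excluded; inter-chain pairs always count).
    """
    config = config or StabilityConfig()
    if ensemble.n_frames < 2:
        raise ValueError("force-constant analysis needs at least 2 frames")
    keys = selection.residue_keys
    admissible_res = _admissible_matrix(keys, config.exclusion_width)
    atom_res = np.concatenate(
        [np.full(len(idx), r) for r, idx in enumerate(selection.atom_indices)]
    )
    flat = selection.flat_indices()
    n_sel = len(flat)
    # per-atom admissibility over selected atoms
    admissible = admissible_res[np.ix_(atom_res, atom_res)]
    counts = admissible.sum(axis=1).astype(float)
    empty = np.unique(atom_res[counts == 0])
    if len(empty):
        raise ValueError(
            "residues with no admissible distance partners under exclusion "
            f"width {config.exclusion_width}: {[keys[r] for r in empty]}"
        )
    series = np.empty((ensemble.n_frames, n_sel))
    adm = admissible.astype(float)
    for start in range(0, ensemble.n_frames, chunk_frames):
        block = ensemble.frames[start:start + chunk_frames][:, flat, :]
        diff = block[:, :, None, :] - block[:, None, :, :]
        dist = np.sqrt(np.einsum("fabx,fabx->fab", diff, diff))
        series[start:start + chunk_frames] = (dist * adm).sum(axis=2) / counts
    groups: list[np.ndarray] = []
    offset = 0
    for idx in selection.atom_indices:
        groups.append(np.arange(offset, offset + len(idx)))
        offset += len(idx)
    return DistanceSeries(
        series=series, residue_keys=list(keys),
        residue_names=list(selection.residue_names), atom_groups=groups,
    )


def force_constants(
    series: DistanceSeries, config: StabilityConfig | None = None
) -> ForceConstantProfile:
    """Invert distance fluctuations into per-residue force constants.

    Per atom a: k_a = c k_B T / Var(d_a); the residue value is the
    average of its atoms' force constants (for one-point representations
    the two coincide).  Zero-variance atoms mark the residue rigid and
    yield no numeric value.
    """
    config = config or StabilityConfig()
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames of distances")
    d = series.series
    mean_d = d.mean(axis=0)
    var_d = np.maximum(((d - mean_d) ** 2).mean(axis=0), 0.0)
    energy = config.constant_factor * config.boltzmann * config.temperature
    n_res = len(series.residue_keys)
    k = np.full(n_res, np.nan)
    res_mean = np.empty(n_res)
    res_var = np.empty(n_res)
    rigid = np.zeros(n_res, dtype=bool)
    for r, grp in enumerate(series.atom_groups):
        res_mean[r] = mean_d[grp].mean()
        res_var[r] = var_d[grp].mean()
        if np.any(var_d[grp] == 0.0):
            rigid[r] = True
        else:
            k[r] = (energy / var_d[grp]).mean()
    return ForceConstantProfile(
        residue_keys=list(series.residue_keys),
        residue_names=list(series.residue_names),
        k=k, mean_distance=res_mean, variance=res_var, rigid=rigid,
    )


def bfactors(
    ensemble: ConformationalEnsemble, selection: ResidueSelection
) -> pd.DataFrame:
    """Ensemble B-factors: B_i = (8 pi^2 / 3) <|dr_i|^2>.

    Assumes frames already superposed; the mean squared displacement is
    taken about each atom's ensemble mean and averaged over the
    residue's representative atoms.
    """
    if ensemble.n_frames < 2:
        warnings.warn("single-frame ensemble: B-factors are all zero")
    flat = selection.flat_indices()
    coords = ensemble.frames[:, flat, :]
    disp = coords - coords.mean(axis=0, keepdims=True)
    msd = np.einsum("fax,fax->a", disp, disp) / ensemble.n_frames
    values = np.empty(selection.n_residues)
    offset = 0
    for r, idx in enumerate(selection.atom_indices):
        values[r] = msd[offset:offset + len(idx)].mean()
        offset += len(idx)
    b = (8.0 * np.pi**2 / 3.0) * values
    return profile_frame(selection, b, value_name="bfactor")


# ---------------------------------------------------------------------------
# Residue depth


_VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _frame_depths(
    coords: np.ndarray, radii: np.ndarray, directions: np.ndarray
) -> np.ndarray:
    """Per-atom depth below the solvent-accessible surface of one frame.

    The SAS is sampled as the set of sphere points on each atom's
    expanded sphere (vdW + probe) not buried inside any neighbour's
    expanded sphere; an atom's depth is its centre's distance to the
    nearest surface point.
    """
    n = len(coords)
    tree = cKDTree(coords)
    rmax = radii.max()
    surface_points: list[np.ndarray] = []
    for a in range(n):
        pts = coords[a] + radii[a] * directions
        neighbours = tree.query_ball_point(coords[a], r=radii[a] + rmax)
        neighbours = [b for b in neighbours if b != a]
        keep = np.ones(len(pts), dtype=bool)
        for b in neighbours:
            d2 = np.einsum(
                "px,px->p", pts - coords[b], pts - coords[b]
            )
            keep &= d2 >= (radii[b] - 1e-9) ** 2
        if keep.any():
            surface_points.append(pts[keep])
    if not surface_points:
        raise ValueError("no solvent-accessible surface points found")
    surf = np.vstack(surface_points)
    surf_tree = cKDTree(surf)
    depth, _ = surf_tree.query(coords, k=1)
    return depth


def residue_depth_profile(
    ensemble: ConformationalEnsemble,
    probe_radius: float = 1.4,
    n_sphere_points: int = 96,
) -> DepthProfile:
    """Mean residue depth below the solvent-accessible surface.

    Depth of an atom is the distance from its centre to the nearest SAS
    point; a residue's depth averages its heavy atoms, and the profile
    averages frames.  Deeply buried residues (large depth) are the
    solvent-protected ones in differential comparisons between states.
    """
    top = ensemble.topology
    if top.n_atoms < 2:
        raise ValueError("depth profiling needs at least 2 atoms")
    radii = np.array(
        [_VDW_RADII.get(str(e).upper(), _DEFAULT_RADIUS) for e in top.element]
    ) + probe_radius
    directions = _fibonacci_sphere(n_sphere_points)
    groups = top.atom_indices_by_residue()
    names = top.residue_names()
    keys = list(groups)
    acc = np.zeros(len(keys))
    for f in range(ensemble.n_frames):
        depth = _frame_depths(ensemble.frames[f], radii, directions)
        acc += np.array([depth[groups[k]].mean() for k in keys])
    acc /= ensemble.n_frames
    return DepthProfile(
        residue_keys=keys, residue_names=[names[k] for k in keys], depth=acc
    )


def differential_depth(
    state_a: DepthProfile, state_b: DepthProfile
) -> pd.DataFrame:
    """Per-residue depth difference a - b on the shared residue set.

    Positive values mean increased burial (solvent protection) in state
    a; residues present in only one state are reported via warning and
    dropped.
    """
    da, db = state_a.as_dict(), state_b.as_dict()
    shared = [k for k in state_a.residue_keys if k in db]
    if not shared:
        raise ValueError("depth profiles share no residues")
    mismatched = (set(da) | set(db)) - set(shared)
    if mismatched:
        warnings.warn(f"residues present in only one state: {sorted(mismatched)}")
    names = dict(zip(state_a.residue_keys, state_a.residue_names))
    return pd.DataFrame(
        {
            "chain": [k[0] for k in shared],
            "residue": [f"{k[1]}{k[2]}" if k[2] else str(k[1]) for k in shared],
            "res_name": [names[k] for k in shared],
            "delta_depth": [da[k] - db[k] for k in shared],
        }
    )
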