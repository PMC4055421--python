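"""Superposition, cross-correlation matrices and principal modes.

After least-squares superposition removes overall rotation/translation,
the residue dynamic cross-correlation matrix

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

measures concerted motion: +1 for perfectly in-phase residues, -1 for
anti-correlated ones, ~0 for independent motion.  Principal component
analysis of the 3N coordinate covariance yields the large-amplitude
("low-frequency", in the quasi-harmonic sense) modes used for
mode-averaged mobility profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble_io import ConformationalEnsemble, ResidueKey, ResidueSelection

__all__ = [
    "CorrelationMatrix",
    "ModeSet",
    "superpose",
    "representative_coordinates",
    "cross_correlation",
    "pca_modes",
    "mobility_profile",
]


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray                      # (N, N), in [-1, 1], diag 1
    residue_keys: list[ResidueKey]
    zero_fluctuation: np.ndarray            # bool flags for undefined rows

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")

    def lookup(self) -> dict[ResidueKey, int]:
        return {k: i for i, k in enumerate(self.residue_keys)}


@dataclass
class ModeSet:
    eigenvalues: np.ndarray     # (M,), A^2, descending
    eigenvectors: np.ndarray    # (3N, M), orthonormal columns
    n_residues: int


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ mobile + t ~ ref."""
    mc, rc = mobile.mean(axis=0), ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection: rotation undefined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ mc


def superpose(
    ensemble: ConformationalEnsemble,
    selection: ResidueSelection,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> ConformationalEnsemble:
    """Least-squares fit of every frame onto the iteratively refined mean.

    All selected atoms enter the fit with equal weight; the reference is
    the mean structure, re-estimated until it moves by less than ``tol``
    A RMSD.  The fitted transform is applied to all atoms of the frame.
    """
    if ensemble.n_frames < 2:
        raise ValueError("superposition needs at least 2 frames")
    flat = selection.flat_indices()
    frames = ensemble.frames.copy()
    ref = frames[0, flat, :].copy()
    for _ in range(max_iter):
        for f in range(frames.shape[0]):
            rot, trans = _kabsch(frames[f, flat, :], ref)
            frames[f] = frames[f] @ rot.T + trans
        new_ref = frames[:, flat, :].mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1)))
        ref = new_ref
        if shift < tol:
            break
    return ConformationalEnsemble(
        topology=ensemble.topology, frames=frames,
        frame_interval=ensemble.frame_interval,
    )


def representative_coordinates(
    ensemble: ConformationalEnsemble, selection: ResidueSelection
) -> np.ndarray:
    """One point per residue per frame: centroid of its selection atoms."""
    reps = np.empty((ensemble.n_frames, selection.n_residues, 3))
    for r, idx in enumerate(selection.atom_indices):
        reps[:, r, :] = ensemble.frames[:, idx, :].mean(axis=1)
    return reps


def cross_correlation(
    ensemble: ConformationalEnsemble,
    selection: ResidueSelection,
    assume_superposed: bool = True,
) -> CorrelationMatrix:
    """Residue dynamic cross-correlation matrix over the ensemble.

    Expects superposed frames (set ``assume_superposed=False`` to fit
    here).  Residues with zero fluctuation have undefined correlations;
    their off-diagonal entries are set to 0 and flagged.
    """
    if ensemble.n_frames < 3:
        raise ValueError("cross-correlation needs at least 3 frames")
    if not assume_superposed:
        ensemble = superpose(ensemble, selection)
    reps = representative_coordinates(ensemble, selection)
    disp = reps - reps.mean(axis=0, keepdims=True)
    inner = np.einsum("fix,fjx->ij", disp, disp) / ensemble.n_frames
    msd = np.diag(inner).copy()
    zero = msd <= 0.0
    denom = np.sqrt(np.outer(np.where(zero, 1.0, msd), np.where(zero, 1.0, msd)))
    c = inner / denom
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(
        matrix=c, residue_keys=list(selection.residue_keys),
        zero_fluctuation=zero,
    )


def pca_modes(
    ensemble: ConformationalEnsemble,
    selection: ResidueSelection,
    n_modes: int | None = None,
) -> ModeSet:
    """Principal components of the 3N residue-coordinate covariance.

    Modes are sorted by decreasing variance; by the quasi-harmonic
    correspondence the largest-variance components are the low-frequency
    functional motions.
    """
    reps = representative_coordinates(ensemble, selection)
    n_res = reps.shape[1]
    flat = reps.reshape(ensemble.n_frames, 3 * n_res)
    flat = flat - flat.mean(axis=0, keepdims=True)
    cov = flat.T @ flat / ensemble.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    if n_modes is not None:
        if n_modes > 3 * n_res:
            warnings.warn(
                f"n_modes={n_modes} exceeds 3N={3 * n_res}; clamping"
            )
            n_modes = 3 * n_res
        evals, evecs = evals[:n_modes], evecs[:, :n_modes]
    return ModeSet(eigenvalues=evals, eigenvectors=evecs, n_residues=n_res)


def mobility_profile(modes: ModeSet, n_use: int = 3) -> np.ndarray:
    """Per-residue displacement amplitude over the top ``n_use`` modes.

    amplitude_i = sqrt( sum_m lambda_m |v_m,i|^2 ), summing the three
    Cartesian components of residue i in each retained eigenvector.
    """
    if n_use < 1:
        raise ValueError("n_use must be at least 1")
    if n_use > len(modes.eigenvalues):
        raise ValueError(
            f"n_use={n_use} exceeds the {len(modes.eigenvalues)} retained modes"
        )
    comp = modes.eigenvectors[:, :n_use].reshape(modes.n_residues, 3, n_use)
    weight = np.einsum("rxm,m->r", comp**2, modes.eigenvalues[:n_use])
    return np.sqrt(weight)
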