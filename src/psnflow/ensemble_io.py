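"""Conformational-ensemble I/O and residue-indexed coordinate model.

The pipeline's unit of input is a conformational ensemble: a fixed
atom/residue topology plus one coordinate set per frame (an MD trajectory,
a multi-model PDB, or a synthetic ensemble).  Residues are keyed by
``(chain id, author residue number, insertion code)`` and are never
renumbered; all coordinates are in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ResidueKey",
    "Structure",
    "ConformationalEnsemble",
    "ResidueSelection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "load_trajectory",
    "select_residue_atoms",
    "write_profile",
    "read_profile",
]

#: (chain id, author residue number, insertion code)
ResidueKey = tuple[str, int, str]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "DOD"})


@dataclass
class Structure:
    """Static topology: per-atom annotations plus one coordinate set."""

    serial: np.ndarray          # int, atom serial numbers
    atom_name: np.ndarray      # str
    res_name: np.ndarray       # str
    chain_id: np.ndarray       # str
    res_id: np.ndarray         # int, author numbering
    ins_code: np.ndarray       # str, '' when absent
    element: np.ndarray        # str
    coords: np.ndarray         # (n_atoms, 3) float64, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_name)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{n} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def residue_keys(self) -> list[ResidueKey]:
        """Unique residue keys in order of first appearance."""
        keys: list[ResidueKey] = []
        seen: set[ResidueKey] = set()
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            key = (str(c), int(r), str(i))
            if key not in seen:
                seen.add(key)
                keys.append(key)
        return keys

    def atom_indices_by_residue(self) -> dict[ResidueKey, np.ndarray]:
        groups: dict[ResidueKey, list[int]] = {}
        for idx, (c, r, i) in enumerate(
            zip(self.chain_id, self.res_id, self.ins_code)
        ):
            groups.setdefault((str(c), int(r), str(i)), []).append(idx)
        return {k: np.asarray(v, dtype=int) for k, v in groups.items()}

    def residue_names(self) -> dict[ResidueKey, str]:
        names: dict[ResidueKey, str] = {}
        for c, r, i, nm in zip(
            self.chain_id, self.res_id, self.ins_code, self.res_name
        ):
            names.setdefault((str(c), int(r), str(i)), str(nm))
        return names


@dataclass
class ConformationalEnsemble:
    """Frames of Cartesian coordinates over a fixed topology."""

    topology: Structure
    frames: np.ndarray          # (n_frames, n_atoms, 3)
    frame_interval: str | float = "unitless"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, n_atoms, 3) array")
        if self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} incompatible with "
                f"topology of {self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, index: int) -> Structure:
        """Topology with the coordinates of one frame."""
        s = self.topology
        return Structure(
            serial=s.serial, atom_name=s.atom_name, res_name=s.res_name,
            chain_id=s.chain_id, res_id=s.res_id, ins_code=s.ins_code,
            element=s.element, coords=self.frames[index].copy(),
        )


@dataclass
class ResidueSelection:
    """Per-residue atom-index lists under a representation mode.

    Modes: ``"calpha"`` (one CA per residue), ``"all"`` (every retained
    atom), ``"sidechain"`` (heavy side-chain atoms; glycine falls back to
    CA so every residue stays a network node).
    """

    mode: str
    residue_keys: list[ResidueKey]
    atom_indices: list[np.ndarray]
    residue_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.residue_keys) != len(self.atom_indices):
            raise ValueError("keys and atom index lists differ in length")
        for key, idx in zip(self.residue_keys, self.atom_indices):
            if len(idx) == 0:
                raise ValueError(f"residue {key} has no atoms selected")

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)

    def flat_indices(self) -> np.ndarray:
        return np.concatenate(self.atom_indices)


# ---------------------------------------------------------------------------
# PDB reading / writing


def _scan_model_atom_counts(path: Path) -> list[int]:
    """Count ATOM/HETATM records per MODEL block (diagnostic fallback)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model = True
                current = 0
            elif rec.startswith("ENDMDL"):
                counts.append(current)
                in_model = False
            elif rec.startswith(("ATOM", "HETATM")):
                current += 1
    if not saw_model:
        counts = [current]
    elif in_model:
        counts.append(current)
    return counts


def read_multimodel_pdb(
    path: str | Path,
    keep_hetero: bool = False,
) -> ConformationalEnsemble:
    """Read a multi-model PDB into an ensemble (one frame per MODEL).

    Hydrogens, waters and (by default) heteroatoms are dropped; the
    topology is taken from the first model.  Mismatched atom counts
    between models are a hard error naming the offending model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        counts = _scan_model_atom_counts(path)
        bad = [
            m + 1 for m, c in enumerate(counts) if c != counts[0]
        ]
        if bad:
            raise ValueError(
                f"{path}: atom count mismatch across models; model(s) "
                f"{bad} have {[counts[b - 1] for b in bad]} atoms while "
                f"model 1 has {counts[0]}"
            ) from exc
        raise ValueError(f"{path}: unreadable PDB records: {exc}") from exc

    mask = stack.element != "H"
    mask &= stack.element != "D"
    mask &= ~np.isin(stack.res_name, list(_WATER_NAMES))
    if not keep_hetero:
        mask &= ~stack.hetero
    stack = stack[..., mask]
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms retained after filtering")

    ins = stack.ins_code if "ins_code" in stack.get_annotation_categories() \
        else np.full(stack.array_length(), "", dtype="U1")
    serial = (
        stack.atom_id
        if "atom_id" in stack.get_annotation_categories()
        else np.arange(1, stack.array_length() + 1)
    )
    topology = Structure(
        serial=np.asarray(serial, dtype=int),
        atom_name=np.asarray(stack.atom_name, dtype="U6"),
        res_name=np.asarray(stack.res_name, dtype="U5"),
        chain_id=np.asarray(stack.chain_id, dtype="U4"),
        res_id=np.asarray(stack.res_id, dtype=int),
        ins_code=np.asarray(ins, dtype="U1"),
        element=np.asarray(stack.element, dtype="U2"),
        coords=stack.coord[0].astype(float),
    )
    return ConformationalEnsemble(
        topology=topology, frames=stack.coord.astype(float)
    )


def _to_atom_array_stack(ensemble: ConformationalEnsemble) -> struc.AtomArrayStack:
    s = ensemble.topology
    n = s.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord[:] = ensemble.frames
    stack.chain_id = s.chain_id.astype("U4")
    stack.res_id = s.res_id.astype(int)
    stack.ins_code = s.ins_code.astype("U1")
    stack.res_name = s.res_name.astype("U5")
    stack.atom_name = s.atom_name.astype("U6")
    stack.element = s.element.astype("U2")
    stack.hetero = np.zeros(n, dtype=bool)
    stack.set_annotation("atom_id", s.serial.astype(int))
    return stack


def write_multimodel_pdb(
    ensemble: ConformationalEnsemble, path: str | Path
) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks)."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(ensemble))
    pdb.write(str(Path(path)))


def load_trajectory(
    topology_path: str | Path, trajectory_path: str | Path
) -> ConformationalEnsemble:
    """Optional adapter: binary trajectory (DCD/XTC/...) + PDB topology.

    Requires mdtraj; the rest of the pipeline never depends on it.
    """
    try:
        import mdtraj
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "binary trajectory reading requires the optional mdtraj "
            "dependency; convert to multi-model PDB instead"
        ) from exc
    traj = mdtraj.load(str(trajectory_path), top=str(topology_path))
    top = traj.topology
    names, resnames, chains, resids, elements = [], [], [], [], []
    for atom in top.atoms:
        names.append(atom.name)
        resnames.append(atom.residue.name)
        chains.append(atom.residue.chain.chain_id or "A")
        resids.append(atom.residue.resSeq)
        elements.append(atom.element.symbol if atom.element else "")
    n = top.n_atoms
    coords = traj.xyz.astype(float) * 10.0  # nm -> Angstrom
    topology = Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.asarray(names, dtype="U6"),
        res_name=np.asarray(resnames, dtype="U5"),
        chain_id=np.asarray(chains, dtype="U4"),
        res_id=np.asarray(resids, dtype=int),
        ins_code=np.full(n, "", dtype="U1"),
        element=np.asarray(elements, dtype="U2"),
        coords=coords[0],
    )
    ens = ConformationalEnsemble(topology=topology, frames=coords)
    mask = topology.element != "H"
    return _subset_ensemble(ens, np.where(mask)[0])


def _subset_ensemble(
    ensemble: ConformationalEnsemble, indices: np.ndarray
) -> ConformationalEnsemble:
    s = ensemble.topology
    topology = Structure(
        serial=s.serial[indices], atom_name=s.atom_name[indices],
        res_name=s.res_name[indices], chain_id=s.chain_id[indices],
        res_id=s.res_id[indices], ins_code=s.ins_code[indices],
        element=s.element[indices], coords=s.coords[indices],
    )
    return ConformationalEnsemble(
        topology=topology, frames=ensemble.frames[:, indices, :],
        frame_interval=ensemble.frame_interval,
    )


# ---------------------------------------------------------------------------
# Residue selections


_MODES = ("calpha", "all", "sidechain")


def select_residue_atoms(
    source: ConformationalEnsemble | Structure, mode: str
) -> ResidueSelection:
    """Map every residue to its representative atom indices.

    ``sidechain`` keeps heavy side-chain atoms (backbone N/CA/C/O/OXT and
    hydrogens excluded); glycine, having no heavy side chain, is
    represented by its alpha carbon so that residue-complete profiles and
    networks remain possible.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown selection mode {mode!r}; use one of {_MODES}")
    top = source.topology if isinstance(source, ConformationalEnsemble) else source
    groups = top.atom_indices_by_residue()
    names = top.residue_names()
    keys: list[ResidueKey] = []
    indices: list[np.ndarray] = []
    missing: list[ResidueKey] = []
    for key, idx in groups.items():
        atom_names = top.atom_name[idx]
        elements = top.element[idx]
        heavy = idx[(elements != "H") & (elements != "D")]
        heavy_names = top.atom_name[heavy]
        if mode == "all":
            chosen = heavy
        elif mode == "calpha":
            chosen = heavy[heavy_names == "CA"]
            if len(chosen) == 0:
                missing.append(key)
                continue
        else:  # sidechain
            chosen = heavy[~np.isin(heavy_names, list(BACKBONE_NAMES))]
            if len(chosen) == 0:
                # glycine (or stripped residue) fallback: alpha carbon
                chosen = heavy[heavy_names == "CA"]
            if len(chosen) == 0:
                missing.append(key)
                continue
        if len(chosen) == 0:
            missing.append(key)
            continue
        keys.append(key)
        indices.append(np.asarray(chosen, dtype=int))
    if missing:
        raise ValueError(
            f"residues with no atoms under mode {mode!r} and no fallback: "
            f"{missing}"
        )
    return ResidueSelection(
        mode=mode, residue_keys=keys, atom_indices=indices,
        residue_names=[names[k] for k in keys],
    )


# ---------------------------------------------------------------------------
# Profile tables


def write_profile(
    profile: pd.DataFrame | dict, path: str | Path, value_name: str = "value"
) -> None:
    """Write a per-residue value series as TSV.

    Columns: chain, residue number (with insertion code appended),
    residue name, value.  Ordering follows the profile's own order.
    """
    if isinstance(profile, dict):
        rows = [
            {
                "chain": k[0],
                "residue": f"{k[1]}{k[2]}" if len(k) > 2 and k[2] else str(k[1]),
                "res_name": "",
                value_name: v,
            }
            for k, v in profile.items()
        ]
        df = pd.DataFrame(rows, columns=["chain", "residue", "res_name", value_name])
    else:
        df = profile
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", dtype={"chain": str, "residue": str})


def profile_frame(
    selection: ResidueSelection,
    values: Sequence[float] | np.ndarray,
    value_name: str = "value",
    **extra_columns: Iterable,
) -> pd.DataFrame:
    """Assemble a residue-indexed profile DataFrame for a selection."""
    values = np.asarray(values)
    if len(values) != selection.n_residues:
        raise ValueError("value series length does not match selection")
    df = pd.DataFrame(
        {
            "chain": [k[0] for k in selection.residue_keys],
            "residue": [
                f"{k[1]}{k[2]}" if k[2] else str(k[1])
                for k in selection.residue_keys
            ],
            "res_name": selection.residue_names
            or [""] * selection.n_residues,
            value_name: values,
        }
    )
    for name, col in extra_columns.items():
        df[name] = list(col)
    return df
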