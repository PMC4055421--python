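import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from psnflow.ensemble_io import ConformationalEnsemble, Structure


def gly_structure(coords: np.ndarray, chain_id: str = "A") -> Structure:
    """One-CA-per-residue glycine chain over given coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.full(n, "CA", dtype="U6"),
        res_name=np.full(n, "GLY", dtype="U5"),
        chain_id=np.full(n, chain_id, dtype="U4"),
        res_id=np.arange(1, n + 1),
        ins_code=np.full(n, "", dtype="U1"),
        element=np.full(n, "C", dtype="U2"),
        coords=coords,
    )


def gly_ensemble(frames: np.ndarray, chain_id: str = "A") -> ConformationalEnsemble:
    frames = np.asarray(frames, dtype=float)
    return ConformationalEnsemble(
        topology=gly_structure(frames[0], chain_id), frames=frames
    )


@pytest.fixture
def contact_fixture():
    from psnflow.synthetic_data import make_contact_fixture

    return make_contact_fixture()


@pytest.fixture(scope="session")
def gaussian_study():
    """A small Gaussian-network ensemble with its analytic covariance,
    shared by the heavier statistical-recovery tests."""
    from psnflow.synthetic_data import (
        build_toy_chain,
        gnm_from_structure,
        sample_gaussian_ensemble,
    )

    chain = build_toy_chain(12, "extended", seed=7)
    model = gnm_from_structure(chain, cutoff=8.0, scale=0.5)
    ensemble, cov = sample_gaussian_ensemble(model, n_frames=20_000, seed=11)
    return model, ensemble, cov
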