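"""Shared fixtures: toy molecules and cached synthetic ESP records.

The synthetic records use a coarser grid than the reference protocol
(fewer layers, lower density) purely to keep the suite fast; the recovery
properties under test are exact-model properties and do not depend on the
sampling density.
"""

import numpy as np
import pytest
from hypothesis import settings

from dpolkit.chem_core import Molecule, PolarizabilityTypeSet
from dpolkit.grid import GridSpec
from dpolkit.synthetic import (
    default_ground_truth,
    make_toy_set,
    synth_esp_records,
)

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

COARSE_GRID = GridSpec(n_layers=3, density_per_angstrom2=1.0)


@pytest.fixture(scope="session")
def toy_set():
    return make_toy_set(seed=0)


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def coarse_grid_spec():
    return COARSE_GRID


@pytest.fixture(scope="session")
def synthetic_records(toy_set, truth):
    """(molecule, baseline, diffs) for two conformers of every toy."""
    out = []
    for confs in toy_set:
        for mol in confs[:2]:
            baseline, diffs = synth_esp_records(mol, truth, COARSE_GRID)
            out.append((mol, baseline, diffs))
    return out


@pytest.fixture(scope="session")
def element_skeleton():
    return PolarizabilityTypeSet(
        "element", [("C", None), ("H", None), ("O", None), ("N", None)])


@pytest.fixture
def water_like():
    """A bent triatomic toy (O at origin, two H) for hand checks."""
    coords = np.array([[0.0, 0.0, 0.0],
                       [0.9572, 0.0, 0.0],
                       [-0.2399872, 0.9266272, 0.0]])
    return Molecule.from_angstrom(
        ["O", "H", "H"], coords, [(0, 1, 1), (0, 2, 1)])


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
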