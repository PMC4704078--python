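"""Shared fixtures: one small tetragonal scene reused across modules.

Everything is generated programmatically from fixed seeds; heavier
session-scoped objects (truth, frames, an EMC fit) are built once.
"""

import numpy as np
import pytest

from emcryst import (
    DetectorGeometry,
    EMCModel,
    ReciprocalGrid,
    RotationSet,
    UnitCell,
)
from emcryst.simulate import make_ground_truth, simulate_dataset

PEAK_SIGMA_ASTAR = 0.13


@pytest.fixture(scope="session")
def cell():
    return UnitCell(32.0, 36.0)


@pytest.fixture(scope="session")
def grid(cell):
    return ReciprocalGrid.from_cell(cell.a_star, 7, 63)


@pytest.fixture(scope="session")
def geom():
    return DetectorGeometry(48, 48, 0.30, 33.0, 1.54, (24.0, 24.0))


@pytest.fixture(scope="session")
def rotations():
    return RotationSet.uniform(60)


@pytest.fixture(scope="session")
def truth(cell, grid):
    return make_ground_truth(cell, grid, PEAK_SIGMA_ASTAR * cell.a_star, rng_seed=11)


@pytest.fixture(scope="session")
def frames(truth, geom, rotations):
    return simulate_dataset(truth, geom, rotations, 4000, 200.0, 0.8, rng_seed=12)


@pytest.fixture(scope="session")
def calibration(truth, geom, rotations):
    return truth.calibrate(geom, rotations, 200.0, 0.8)


@pytest.fixture(scope="session")
def emc_fit(frames, geom, rotations, grid, cell, truth):
    """A converged small EMC run shared by convergence/validation tests."""
    model = EMCModel(frames, geom, rotations, grid, cell=cell,
                     orientation=truth.orientation,
                     peak_sigma_q=PEAK_SIGMA_ASTAR * cell.a_star)
    return model.fit(n_iter=8, rng_seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
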