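"""Shared fixtures: small grids and a coarse benchmark dataset.

Simulation-backed fixtures run on reduced grids so the whole suite stays
fast; the scenario itself (5 time points in (0, 1], 10×5 = 50 pixels,
σ = 10⁻² log-noise, b = 10⁻⁴ offset, truth θ = (0.5, 0.1, 5, 1, 0.1))
is never changed.
"""

from __future__ import annotations

import numpy as np
import pytest

import rdprofile as rd

#: coarse grid used for simulation-backed unit tests
TEST_NX = 20
#: loose-but-safe integrator tolerances for test-size problems
TEST_RTOL = 1e-6
TEST_ATOL = 1e-9


@pytest.fixture(scope="session")
def grid():
    return rd.DomainGrid(nx=TEST_NX)


@pytest.fixture(scope="session")
def source(grid):
    return rd.build_y_source(grid)


@pytest.fixture(scope="session")
def truth():
    return rd.default_true_parameters()


@pytest.fixture(scope="session")
def dataset(grid, source, truth):
    """Benchmark scenario on the coarse test grid, seed 1."""
    return rd.generate_dataset(truth=truth, seed=1, grid=grid, source=source,
                               rtol=TEST_RTOL, atol=TEST_ATOL)


@pytest.fixture(scope="session")
def ctx(dataset):
    return rd.ModelContext(grid=dataset.grid, source=dataset.source,
                           rtol=TEST_RTOL, atol=TEST_ATOL)


@pytest.fixture(scope="session")
def traj(truth, source, grid):
    """Trajectory at the true parameters on the test grid."""
    return rd.simulate(truth, source, grid, np.linspace(0.2, 1.0, 5),
                       rtol=TEST_RTOL, atol=TEST_ATOL)
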