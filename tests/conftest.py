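import warnings

import numpy as np
import pytest

import siftwin as st
from siftwin.synthetic import Grid


@pytest.fixture(scope="session")
def table():
    return st.default_parameter_table()


@pytest.fixture()
def vec(table):
    return st.build_parameter_vector(table)


@pytest.fixture(scope="session")
def small_grid():
    # smallest grid satisfying the per-PFT anchor guarantees
    return Grid(n_lat=24, n_lon=24)


@pytest.fixture(scope="session")
def small_scenario(small_grid):
    """Two-year, zero-perturbation scenario shared by fast tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return st.make_scenario(grid=small_grid, years=2, seed=11, perturbation=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def constant_forcing():
    """Constant benign forcing on a handful of cells (1 year)."""
    n_cells = 4
    n_days = 365
    return st.Forcing(
        air_temperature=np.full((n_days, n_cells), 24.0),
        shortwave=np.full((n_days, n_cells), 300.0),
        soil_moisture=np.full((n_days, n_cells), 0.9),
        lat=np.array([5.0, 10.0, 15.0, 20.0]),
        lon=np.array([0.0, 10.0, 20.0, 30.0]),
    )
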