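import numpy as np
import pytest
from hypothesis import settings

from censorfilter.exact_filter import (
    gaussian_grid_posterior,
    make_grid,
    transition_matrix,
)
from censorfilter.model import ModelParameters, steady_state_moments

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Reference study parameters (the model defaults)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def grid(params):
    return make_grid(params)


@pytest.fixture(scope="session")
def kernel(params, grid):
    return transition_matrix(grid, params)


@pytest.fixture(scope="session")
def stationary_prior(params, grid):
    mean, sd = steady_state_moments(params)
    return gaussian_grid_posterior(grid, mean, sd, trial_index=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
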