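import numpy as np
import pytest

from gardenbias import (
    GrowthParams,
    make_grid_layout,
    make_initial_sizes,
    make_posterior_draws,
)


@pytest.fixture(scope="session")
def default_layout():
    """The study-scale garden: 470 positions, 22 mortalities."""
    return make_grid_layout(seed=11)


@pytest.fixture(scope="session")
def default_sizes(default_layout):
    return make_initial_sizes(default_layout, seed=12)


@pytest.fixture()
def small_layout():
    """A quick 6x5 garden with a few gaps for unit tests."""
    return make_grid_layout(n_positions=30, n_cols=6, dx=1.0, dy=1.5,
                            n_dead=3, seed=7)


@pytest.fixture()
def toy_params():
    return GrowthParams(
        alpha=[1.0, 0.5], beta=[0.5, 0.4], gamma=[-0.4, -0.2],
        c=[1.0, 0.8], b=-0.55, sigma=0.1,
    )


@pytest.fixture(scope="session")
def small_draws():
    return make_posterior_draws(n_draws=30, seed=13)
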