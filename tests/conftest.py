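import numpy as np
import pytest

from alpshift.grids import GridSpec
from alpshift.synthetic import build_landscape, simulate_species


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(60, 60, 100.0, fine_to_coarse_factor=10)


@pytest.fixture(scope="session")
def landscape(small_grid):
    return build_landscape(small_grid, seed=11)


@pytest.fixture(scope="session")
def unbiased_world(small_grid, landscape):
    """Species sampled without observer bias (detection probability constant)."""
    return simulate_species(
        landscape,
        n_species=6,
        seed=21,
        expected_points=1200,
        bias_params={"w_road": 0.0, "w_city": 0.0, "w_country": 0.0, "favoured_region": 0},
    )


@pytest.fixture(scope="session")
def biased_world(small_grid, landscape):
    return simulate_species(landscape, n_species=6, seed=22, expected_points=1200)
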