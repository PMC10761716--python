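import numpy as np
import pytest

from treethreat.grid import GridSpec, Raster
from treethreat.synthetic import SyntheticConfig, gen_world


@pytest.fixture(scope="session")
def small_world():
    """A 30-species world at coarse resolution with forced minimal species."""
    config = SyntheticConfig(n_species=30, n_minimal_species=3, resolution=0.1, seed=11)
    return gen_world(config)


@pytest.fixture
def rng():
    return np.random.default_rng(202409)


@pytest.fixture
def unit_grid():
    """10x10 grid of 0.1-degree cells starting at (0, 0)."""
    return GridSpec(lon_min=0.0, lat_min=0.0, resolution=0.1, n_cols=10, n_rows=10)


def constant_raster(grid: GridSpec, value, dtype=float) -> Raster:
    return Raster(grid, np.full(grid.shape, value, dtype=dtype))
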