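import numpy as np
import pytest

from timberzone.grids import GridTransform
from timberzone.synthetic import TruthParams, generate_climate_grid, true_suitability_surface


@pytest.fixture(scope="session")
def small_grid():
    return generate_climate_grid((24, 32), seed=11)


@pytest.fixture(scope="session")
def truth():
    return TruthParams()


@pytest.fixture(scope="session")
def truth_surface(small_grid, truth):
    return true_suitability_surface(small_grid, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_transform():
    """1-km cells anchored at the default origin (handy for toy lattices)."""
    return GridTransform(cell_deg=1.0 / 111.19492664455873)
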