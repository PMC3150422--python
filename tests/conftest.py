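import numpy as np
import pytest

from rirrsim import fixtures
from rirrsim.geometry import make_regular_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cardiomyocyte_geometry():
    return make_regular_layout()


@pytest.fixture
def mini():
    """Mini world: (RunConfig, CellGeometry) for fast integration tests."""
    return fixtures.make_mini_fixture()
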