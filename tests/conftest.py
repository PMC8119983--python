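import numpy as np
import pytest

from radonmc.fixtures import make_toy_geometry, make_toy_library
from radonmc.physics import StoppingPowerTable
from radonmc.tissue import place_nuclei


@pytest.fixture(scope="session")
def table():
    return StoppingPowerTable.default()


@pytest.fixture(scope="session")
def toy_library():
    return make_toy_library(seed=0)


@pytest.fixture(scope="session")
def toy_geometry():
    return make_toy_geometry(seed=0)


@pytest.fixture(scope="session")
def small_geometry():
    """100 x 100 um sub-segment (~540 nuclei): enough statistics for
    ordering and balance checks at test-friendly run times."""
    return place_nuclei(np.random.default_rng(12), 100.0, 100.0)
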