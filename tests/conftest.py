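import numpy as np
import pytest

from atrophynet import CorticalSurface, make_atlas, make_icosphere


@pytest.fixture(scope="session")
def ico1():
    return make_icosphere(1)


@pytest.fixture(scope="session")
def ico3():
    return make_icosphere(3, scale=100.0)


@pytest.fixture(scope="session")
def surf3(ico3):
    """Single-hemisphere level-3 surface (642 vertices, 100 mm sphere)."""
    return CorticalSurface(ico3)


@pytest.fixture(scope="session")
def bilateral3():
    """Bilateral level-3 surface (1284 vertices)."""
    return CorticalSurface.bilateral(3, 100.0)


@pytest.fixture(scope="session")
def atlas68(bilateral3):
    """34 regions per hemisphere on the bilateral level-3 surface."""
    return make_atlas(bilateral3, 34, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
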