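import numpy as np
import pytest

from hydraplate import meniscus as mn


@pytest.fixture(scope="session")
def fluid():
    return mn.FluidParams()


@pytest.fixture(scope="session")
def fluid_g0():
    return mn.FluidParams(gravity=0.0)


@pytest.fixture(scope="session")
def well():
    return mn.WellGeometry()


@pytest.fixture(scope="session")
def wetting():
    return mn.WettingParams()


@pytest.fixture(scope="session")
def solver(fluid):
    """Shared cap-family cache: protocol tests reuse the same fluid."""
    return mn.CapSolver(fluid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
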