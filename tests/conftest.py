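import numpy as np
import pytest

import crowdflux as cf


@pytest.fixture(scope="session")
def params():
    """Printed coarse-grained constants (default survival demand)."""
    return cf.MinimalModelParams()


@pytest.fixture(scope="session")
def two_cell_params():
    """Parameters for which all four donor/acceptor regimes exist."""
    return cf.two_cell_test_params()


@pytest.fixture(scope="session")
def th(params):
    return cf.thresholds(params)


@pytest.fixture(scope="session")
def th2(two_cell_params):
    return cf.thresholds(two_cell_params)


@pytest.fixture
def unit_square():
    ids = ["x", "y"]
    A = np.vstack([np.eye(2), -np.eye(2)])
    b = np.array([1.0, 1.0, 0.0, 0.0])
    return cf.FluxPolytope(ids, ids, np.eye(2), np.zeros(2), A, b)


@pytest.fixture
def triangle():
    return cf.make_fixture("triangle-toy")


@pytest.fixture
def aniso_box():
    return cf.make_fixture("anisotropic-box")


@pytest.fixture(scope="session")
def minimal_poly(params):
    """Reduced polytope of the single-cell fixture at U_G = 0.5."""
    net = cf.minimal_as_network(params, U_G=0.5)
    spec = cf.default_crowding_spec(params)
    return net, spec, cf.rref_reduce(net, crowding=spec)
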