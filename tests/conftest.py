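import numpy as np
import pytest

from capatp.chamber import ChamberCondition
from capatp.driver import run_steady_state
from capatp.fixtures import make_mini_network, make_tiny_network
from capatp.params import AtpParams, TransportParams


@pytest.fixture(scope="session")
def params():
    return TransportParams()


@pytest.fixture(scope="session")
def atp_params():
    return AtpParams()


@pytest.fixture(scope="session")
def control_condition():
    return ChamberCondition(shape="none", outlet_po2=None)


@pytest.fixture(scope="session")
def tiny_geom(params):
    """4-capillary reduced network (44 x 120 x 60 um, h = 4 um)."""
    return make_tiny_network(4.0, params)


@pytest.fixture(scope="session")
def mini_geom(params):
    """12-capillary reduced network (108 x 266 x 100 um, h = 4 um)."""
    return make_mini_network(4.0, params)


@pytest.fixture(scope="session")
def tiny_control(tiny_geom, params, control_condition):
    """Converged zero-flux control on the tiny network (shared)."""
    return run_steady_state(tiny_geom, params, control_condition)
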