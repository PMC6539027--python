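import numpy as np
import pytest

from redoxclock import ParameterSet
from redoxclock.detailed_model import CORRESPONDENCE
from redoxclock.simulate import discard_transient, integrate


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def ref_traj(default_params):
    """Post-transient reference limit cycle of the reduced model."""
    return discard_transient(integrate("reduced", default_params, t_end=500.0, dt_out=0.01), 240.0)


@pytest.fixture(scope="session")
def full_traj(default_params):
    """Post-transient limit cycle of the full five-variable model."""
    return discard_transient(integrate("full", default_params, t_end=500.0, dt_out=0.01), 240.0)


@pytest.fixture(scope="session")
def detailed_traj():
    """Post-transient limit cycle of the detailed model (correspondence rates)."""
    return discard_transient(integrate("detailed", CORRESPONDENCE, t_end=700.0, dt_out=0.02), 300.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240509)
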