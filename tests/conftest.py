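import numpy as np
import pytest
from hypothesis import settings

from dscsim import PhysicsConstants, TimeGrid

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> PhysicsConstants:
    return PhysicsConstants()


@pytest.fixture(scope="session")
def fine_grid() -> TimeGrid:
    return TimeGrid(dt=0.1, duration=120.0)


@pytest.fixture(scope="session")
def gamma_b0():
    """Angular frequency factor gamma*B0 at 3T (rad/s)."""
    return 2 * np.pi * 42.6e6 * 3.0
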