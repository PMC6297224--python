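import numpy as np
import pytest
from hypothesis import settings

from rpospulse import SimParams

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    """Default (calibrated) parameters with a short run for unit tests."""
    return SimParams(t_total=50.0, t_burnin=20.0)


@pytest.fixture
def quiet_params():
    """No reactions, no molecules: a cell that never grows."""
    return SimParams(k_rp=0.0, k_rd=0.0, k_gp=0.0, k_gd=0.0, r0=0, g0=0,
                     t_total=10.0, t_burnin=1.0)
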