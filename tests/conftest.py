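import numpy as np
import pytest

from crccsim import constant_protocol, default_parameters, simulate

ARM_LEVELS = {
    "control": (0.0, 0.0),
    "ATV": (0.0, 5.0),
    "TZB": (1.0, 0.0),
    "combo": (1.0, 5.0),
}


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def four_arm_sims(params):
    """The four clamped study arms simulated for 30 days from the standard
    initial condition (shared across analysis and acceptance tests)."""
    return {
        name: simulate(params, constant_protocol(T, A, horizon_days=30.0))
        for name, (T, A) in ARM_LEVELS.items()
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
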