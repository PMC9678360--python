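import numpy as np
import pytest

from polegrowth import SimulationConfig


@pytest.fixture
def exact_config():
    """Constant-rate configuration: growth is deterministic given the seed."""
    return SimulationConfig(
        rate_old=0.14,
        rate_new=0.06,
        rate_cv=0.0,
        pole_share_sd=0.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
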