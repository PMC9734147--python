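import numpy as np
import pytest

from aabci.simulator import (
    NoisyCenterOutController,
    NoisyDiscreteController,
    SimConfig,
    make_templates,
    simulate_centerout_session,
    simulate_discrete_session,
)


@pytest.fixture(scope="session")
def small_config():
    """Reduced geometry (4 channels, 600 features) for fast tests."""
    return SimConfig(n_channels=4, cmtp_snr=0.4)


@pytest.fixture(scope="session")
def discrete_stream(small_config):
    rng = np.random.default_rng(7)
    templates = make_templates(small_config, rng)
    return simulate_discrete_session(
        small_config,
        templates,
        NoisyDiscreteController(0.65),
        240.0,
        rng=np.random.default_rng(11),
    )


@pytest.fixture(scope="session")
def continuous_stream(small_config):
    rng = np.random.default_rng(8)
    templates = make_templates(small_config, rng, paradigm="continuous")
    return simulate_centerout_session(
        small_config,
        templates,
        NoisyCenterOutController(),
        30,
        rng=np.random.default_rng(12),
    )
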