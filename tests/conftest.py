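import numpy as np
import pytest

from neuropor import SyntheticConfig, generate_experiment
from neuropor.synth import OdorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study configuration for fast end-to-end tests."""
    return SyntheticConfig(
        n_pn=12,
        odor_set=(
            OdorSpec("HEX", "appetitive", 0.62),
            OdorSpec("LOOL", "aversive", 0.29),
        ),
        n_locusts=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)
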