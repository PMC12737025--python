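import numpy as np
import pytest

from phalgrade.synthetic import GeneratorConfig, generate_seedling_state


@pytest.fixture(scope="session")
def zero_noise_config():
    """Generator conditions with a perfect detector."""
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def states_1000(zero_noise_config):
    """A fixed synthetic population shared by the slower tests."""
    return generate_seedling_state(zero_noise_config, 1000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
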