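import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    from balchaos.network import NetworkConfig

    return NetworkConfig(N=300, g=2.0, J0=1.0, I0=1.0)
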