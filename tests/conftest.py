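import numpy as np
import pytest

from ei_netsim.network import NetworkConfig


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config for fast simulation tests (matching 67/33 mix)."""
    return NetworkConfig(n_exc=67, n_inh=33, duration=5.0, burn_in=1.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
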