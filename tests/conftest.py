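import numpy as np
import pytest

from snailtrail.config import CAConfig


@pytest.fixture(scope="session")
def small_config():
    """A small Model 2 lattice exercising every interaction channel."""
    return CAConfig(R=20, P_m=1.0, k=5.0, tau=1 / 160, P_p=0.05,
                    a_n=0.3, a_e=0.4, mode=2, K_IC=8, K_max=80)


@pytest.fixture
def rng():
    return np.random.RandomState(12345)
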