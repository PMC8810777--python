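import numpy as np
import pytest

from territorps import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    return SimulationConfig(L=8, M=1e-3, T_max=10, seed=7).with_k(1.0)
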