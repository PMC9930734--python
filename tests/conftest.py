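import numpy as np
import pytest

from cowcalfsim.config_environment import default_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return default_config()
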