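import numpy as np
import pytest

from cmcsim.cmc_core import SynapticParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    """Homogeneous Table-default parameters for a small population."""
    return SynapticParams.homogeneous(2000)
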