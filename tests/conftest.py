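import numpy as np
import pytest

from iwavesim.config import default_config
from iwavesim.network import build_macrocolumn


@pytest.fixture(scope="session")
def default_network():
    """The full 79-microcolumn macrocolumn (expensive; shared)."""
    return build_macrocolumn(seed=0)


@pytest.fixture(scope="session")
def small_network():
    """A 2-microcolumn network for exhaustive wiring checks."""
    return build_macrocolumn(default_config(n_microcolumns=2), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
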