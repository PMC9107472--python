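import numpy as np
import pytest

from nanodose.nucleation import get_pfc


@pytest.fixture(scope="session")
def pfb():
    return get_pfc("perfluorobutane")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
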