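import numpy as np
import pytest

from poqtl.genmap import default_rat_map, make_map


@pytest.fixture(scope="session")
def rat_map():
    """The default 20-autosome, 140-marker framework map."""
    return default_rat_map()


@pytest.fixture(scope="session")
def small_map():
    """A single 100 cM chromosome with six markers."""
    return make_map({"1": 100.0}, {"1": 6})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
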