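import numpy as np
import pytest

from tepaleo import derive_mite, make_ancestral_element


@pytest.fixture(scope="session")
def element():
    """A 1.3-kb mariner-like element with perfect 28-bp TIRs."""
    return make_ancestral_element(1300, 28, seed=1)


@pytest.fixture(scope="session")
def mite(element):
    """A 550-bp internally deleted derivative keeping both TIRs."""
    return derive_mite(element, 275, 275)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
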