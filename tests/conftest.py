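import numpy as np
import pytest

from nirdose.calibration import reference_fit


@pytest.fixture(scope="session")
def eq1_fit():
    """The published quartic 1064 nm gradient polynomial."""
    return reference_fit(1064)


@pytest.fixture(scope="session")
def eq2_fit():
    """The published quadratic 1270 nm gradient polynomial."""
    return reference_fit(1270)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
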