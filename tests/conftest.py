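import numpy as np
import pytest

from hsdemosaic import canonical_pattern, make_response_set


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pattern4():
    """Canonical bijective 4×4/16-band mosaic."""
    return canonical_pattern(4)


@pytest.fixture
def cube16(rng):
    """Random 8×8×16 cube matching the canonical pattern."""
    return rng.random((8, 8, 16))


@pytest.fixture
def responses16():
    """Small 16-band Gaussian response set on the VNIR grid."""
    return make_response_set(16, np.linspace(400.0, 1000.0, 61), seed=3)
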