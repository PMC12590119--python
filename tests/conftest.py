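import numpy as np
import pytest

from amblyosim import Geometry


@pytest.fixture
def geometry64() -> Geometry:
    """Coarse 64x64 field (3.2 deg at 20 px/deg) for fast fitting tests."""
    return Geometry(3.2, 20.0)


@pytest.fixture
def geometry128() -> Geometry:
    """128x128 field (3.2 deg at 40 px/deg): the scaled-down analysis grid."""
    return Geometry(3.2, 40.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
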