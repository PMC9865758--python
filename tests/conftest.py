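import numpy as np
import pytest

from tomoreduce import ScanGeometry


@pytest.fixture(scope="session")
def small_geom() -> ScanGeometry:
    """16x16 image scanned by 20 sensors at 20 angles (dense-oracle size)."""
    return ScanGeometry(J=20, K=20, N=16)


@pytest.fixture(scope="session")
def tiny_geom() -> ScanGeometry:
    """8x8 image, 10 angles x 8 sensors: fast consistent-system instance."""
    return ScanGeometry(J=8, K=10, N=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
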