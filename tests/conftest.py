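import numpy as np
import pytest
from hypothesis import settings

from suvhist import SUVVolume

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_volume():
    """Build an SUVVolume from data and optional affine (default identity)."""

    def _make(data, affine=None):
        data = np.asarray(data, dtype=float)
        if affine is None:
            affine = np.eye(4)
        return SUVVolume(data=data, affine=np.asarray(affine, dtype=float))

    return _make


@pytest.fixture
def spacing_affine():
    """Diagonal affine with given voxel spacing and origin."""

    def _make(spacing, origin=(0.0, 0.0, 0.0)):
        aff = np.eye(4)
        aff[:3, :3] = np.diag(spacing)
        aff[:3, 3] = origin
        return aff

    return _make
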