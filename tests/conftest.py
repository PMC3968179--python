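import numpy as np
import pytest

from coupledicd.synthetic import default_mask
from coupledicd.volume_io import BrainMask, MaskedTimeSeries


def make_ts(values, tr_seconds=2.0, mask=None):
    """Wrap a V x T array as a MaskedTimeSeries on a trivial mask."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = default_mask(values.shape[0])
    return MaskedTimeSeries(values=values, mask=mask,
                            tr_seconds=tr_seconds, affine=np.eye(4))


def pearson_brute(a, b):
    """Two-pass textbook Pearson correlation (independent oracle)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a.mean(), b.mean()
    num = ((a - am) * (b - bm)).sum()
    den = np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
    return num / den


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_ts(rng):
    """50 voxels x 200 frames of white noise."""
    return make_ts(rng.standard_normal((50, 200)))


@pytest.fixture
def grid_mask():
    """A 4x4x4 all-true mask."""
    return BrainMask(labels=np.ones((4, 4, 4), dtype=bool))
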