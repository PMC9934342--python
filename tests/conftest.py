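import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cilgibbs.geometry import PointPattern, Window


@pytest.fixture
def unit_window():
    return Window(0.0, 1.0, 0.0, 1.0)


@pytest.fixture
def square_300():
    return Window(0.0, 300.0, 0.0, 300.0)


@pytest.fixture
def separated_disks(square_300):
    """25 points pairwise at least 20 um apart, away from the border."""
    rng = np.random.default_rng(7)
    pts = []
    while len(pts) < 25:
        c = rng.uniform(15.0, 285.0, 2)
        if not pts or cdist([c], pts).min() > 20.0:
            pts.append(c)
    return PointPattern(np.asarray(pts), square_300)


@pytest.fixture
def two_blobs():
    """Two well-separated Gaussian blobs (sigma 0.1, centres 4 apart)."""
    rng = np.random.default_rng(11)
    X = np.vstack([
        rng.normal([0.0, 0.0], 0.1, (50, 2)),
        rng.normal([4.0, 4.0], 0.1, (50, 2)),
    ])
    labels = np.array([0] * 50 + [1] * 50)
    return X, labels
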