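import numpy as np
import pytest

from dgne import behavior as beh
from dgne.synthetic import GeneratorParams, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A short synthetic session for fast structural tests."""
    p = GeneratorParams(n_cells=40, duration_s=240, n_planted_nes=8,
                        n_clusters=2, ne_size_mean=8.0, ne_size_min=5)
    return generate_session(p, seed=11)


@pytest.fixture(scope="session")
def default_session():
    """One full-size default session shared across recovery tests."""
    return generate_session(seed=7)


@pytest.fixture(scope="session")
def default_epochs(default_session):
    s, _ = default_session
    return beh.segment_locomotion(s.speed, s.frame_rate)


def brute_force_window_counts(raster, window=3):
    """Independent oracle: count distinct active cells per centered window."""
    n_cells, n_frames = raster.shape
    hw = window // 2
    out = np.zeros(n_frames, dtype=int)
    for t in range(n_frames):
        lo, hi = max(t - hw, 0), min(t + hw + 1, n_frames)
        out[t] = int(np.count_nonzero(raster[:, lo:hi].sum(axis=1) > 0))
    return out
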