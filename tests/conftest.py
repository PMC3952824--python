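import numpy as np
import pytest
from hypothesis import settings

import resectrack as rt
from resectrack.detection_tracking import Track

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def acq():
    return rt.AcquisitionParams()


@pytest.fixture
def render_noise_free():
    return rt.RenderParams(read_noise_sd=0.0, bleach_tau_min=np.inf)


def tracks_from_positions(pos_um: np.ndarray, pixel_size_um: float = 0.065,
                          frames=None) -> list[Track]:
    """Wrap an (n_tracks, n_times, 2) µm position array as pixel-unit tracks."""
    n, m, _ = pos_um.shape
    if frames is None:
        frames = np.arange(m)
    return [Track(i, np.asarray(frames),
                  pos_um[i, :, 0] / pixel_size_um,
                  pos_um[i, :, 1] / pixel_size_um,
                  np.ones(m)) for i in range(n)]


@pytest.fixture
def make_tracks():
    return tracks_from_positions
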