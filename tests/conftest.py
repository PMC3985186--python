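import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnptrack import MicrotubuleAxis, OnAxisTrack, SimConfig

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def horizontal_axis() -> MicrotubuleAxis:
    """15 um axis along +x, minus end at the origin."""
    return MicrotubuleAxis(mt_id="mt0", minus_end=(0.0, 0.0), plus_end=(15000.0, 0.0))


@pytest.fixture
def config_15fps() -> SimConfig:
    return SimConfig(frame_rate=15.0, n_frames=300, loc_noise_sd=8.0, seed=1)


def track_from_displacements(d, frame_interval=1.0 / 15.0, start=7500.0, track_id="t0"):
    """Build an on-axis track whose displacement series is exactly ``d``."""
    s = np.concatenate([[start], start + np.cumsum(np.asarray(d, float))])
    return OnAxisTrack(track_id=track_id, mt_id="mt0", s=s, frame_interval=frame_interval)
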