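import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spherotrack import Calibration, TrackTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(track_points, frame_interval=30.0, fiber_axis_deg=90.0, **cal_kwargs):
    """Build a TrackTable from {track_id: [(frame, x, y), ...]}."""
    rows = []
    sid = 0
    for tid, pts in track_points.items():
        for frame, x, y in pts:
            rows.append((sid, tid, float(x), float(y), int(frame)))
            sid += 1
    spots = pd.DataFrame(rows, columns=["spot_id", "track_id", "x", "y", "frame"])
    cal = Calibration(frame_interval=frame_interval, fiber_axis_deg=fiber_axis_deg, **cal_kwargs)
    return TrackTable(spots=spots, calibration=cal)


def random_table(rng, n_tracks=8, n_frames=10, box=200.0, frame_interval=30.0):
    """Random-walk tracks with random start frames; always >= 2 points each."""
    tracks = {}
    for tid in range(n_tracks):
        start = int(rng.integers(0, max(n_frames - 2, 1)))
        length = int(rng.integers(2, n_frames - start + 1))
        x, y = rng.uniform(0, box, size=2)
        pts = []
        for k in range(length):
            pts.append((start + k, x, y))
            x += rng.normal(0, 8.0)
            y += rng.normal(0, 8.0)
        tracks[tid] = pts
    return make_table(tracks, frame_interval=frame_interval)


@pytest.fixture
def cal30():
    return Calibration(pixel_size=1.0, frame_interval=30.0, fiber_axis_deg=90.0)


@pytest.fixture
def table_345():
    """Track through 3-4-5 triangles: (0,0)->(3,4)->(9,12) at frames 0,1,3."""
    return make_table({0: [(0, 0.0, 0.0), (1, 3.0, 4.0), (3, 9.0, 12.0)]})


@pytest.fixture
def table_zigzag():
    """(0,0)->(3,4)->(6,0): accumulated 10, euclidean 6, ratio 0.6."""
    return make_table({0: [(0, 0.0, 0.0), (1, 3.0, 4.0), (2, 6.0, 0.0)]})
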