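import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from smlmpair import SimulationSpec, simulate_blinks, simulate_cell


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def emitters(rng):
    """Single-channel emitters >= 500 nm apart inside a 250 um^2 circle.

    Rejection-sampled so grouping cannot legitimately merge two distinct
    emitters (they are far beyond the 200 nm merge radius).
    """
    from smlmpair import circle_radius_nm

    R = circle_radius_nm(250.0)
    pts: list[np.ndarray] = []
    while len(pts) < 50:
        r = R * np.sqrt(rng.random())
        theta = rng.random() * 2 * np.pi
        cand = np.array([r * np.cos(theta), r * np.sin(theta)])
        if all(np.hypot(*(cand - q)) >= 500.0 for q in pts):
            pts.append(cand)
    pts = np.asarray(pts)
    return pd.DataFrame(
        {
            "id": np.arange(1, len(pts) + 1, dtype=np.int64),
            "channel": "A",
            "x": pts[:, 0],
            "y": pts[:, 1],
            "n_locs": 1,
            "accuracy": np.nan,
            "frame_first": 1,
            "frame_last": 1,
        }
    )


@pytest.fixture
def blink_table(emitters, rng):
    """Blink-level fixture with ground-truth emitter labels."""
    return simulate_blinks(emitters, rng, sigma=10.0, mean_blinks=5.0, burst_length=100)


def make_loc_table(xs, ys, frames, channel="A", accuracy=None, n_frames_total=None):
    n = len(xs)
    t = pd.DataFrame(
        {
            "channel": channel,
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float),
            "frame": np.asarray(frames, dtype=np.int64),
            "accuracy": np.asarray(accuracy, dtype=float)
            if accuracy is not None
            else np.nan,
            "id": np.arange(1, n + 1, dtype=np.int64),
        }
    )
    t.attrs["n_frames_total"] = int(n_frames_total or (max(frames) if n else 0))
    t.attrs["source"] = "test"
    return t


def make_molecules(points, channel="A", ids=None):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=np.int64)
            if ids is not None
            else np.arange(1, n + 1, dtype=np.int64),
            "channel": channel,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "n_locs": 1,
            "accuracy": np.nan,
            "frame_first": 1,
            "frame_last": 1,
        }
    )
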