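import numpy as np
import pandas as pd
import pytest

from tipcollide import AnalysisConfig, SpotTable, TrackTable


def make_tracks(points, frame_interval=1.0):
    """Build a TrackTable from [(track_id, frame, x, y), ...]."""
    return TrackTable(
        pd.DataFrame(points, columns=["track_id", "frame", "x", "y"]),
        frame_interval=frame_interval,
    )


def make_spots(points, frame_interval=1.0):
    """Build a SpotTable from [(spot_id, frame, x, y, diameter), ...]."""
    return SpotTable(
        pd.DataFrame(points, columns=["spot_id", "frame", "x", "y", "diameter"]),
        frame_interval=frame_interval,
    )


def straight_track(track_id=0, n=5, step=0.25, start=(0.0, 0.0), frame0=0):
    return [
        (track_id, frame0 + i, start[0] + i * step, start[1]) for i in range(n)
    ]


def random_instance(rng, max_tracks=50, max_spots=30, n_frames=50, box=12.0):
    """A random field of short random-walk tracks and jittering spots."""
    n_tracks = int(rng.integers(2, max_tracks + 1))
    n_spots = int(rng.integers(1, max_spots + 1))
    t_rows = []
    for tid in range(n_tracks):
        f0 = int(rng.integers(0, n_frames - 2))
        length = int(rng.integers(2, n_frames - f0 + 1))
        pos = rng.uniform(0, box, size=2)
        for i in range(length):
            t_rows.append((tid, f0 + i, pos[0], pos[1]))
            pos = pos + rng.normal(0, 0.3, size=2)
    s_rows = []
    for sid in range(n_spots):
        anchor = rng.uniform(0, box, size=2)
        diam = rng.uniform(0.2, 1.2)
        f0 = int(rng.integers(0, n_frames // 2))
        length = int(rng.integers(1, n_frames - f0 + 1))
        for i in range(length):
            jit = rng.normal(0, 0.05, size=2)
            s_rows.append((sid, f0 + i, anchor[0] + jit[0], anchor[1] + jit[1], diam))
    return make_tracks(t_rows), make_spots(s_rows)


def bruteforce_contacts(tracks, spots, buffer=0.1, criterion="border"):
    """All-pairs-all-frames contact oracle (no frame grouping).

    Crosses every track point with every spot observation and keeps pairs
    in the same frame whose center distance is under the threshold.
    """
    t = tracks.data
    s = spots.data
    tx = t["x"].to_numpy()[:, None]
    ty = t["y"].to_numpy()[:, None]
    sx = s["x"].to_numpy()[None, :]
    sy = s["y"].to_numpy()[None, :]
    d = np.sqrt((tx - sx) ** 2 + (ty - sy) ** 2)
    same_frame = t["frame"].to_numpy()[:, None] == s["frame"].to_numpy()[None, :]
    diam = s["diameter"].to_numpy()[None, :]
    thresh = diam / 2.0 + buffer if criterion == "border" else diam
    ti, si = np.nonzero(same_frame & (d < thresh))
    rows = [
        (
            t["track_id"].iat[i],
            s["spot_id"].iat[j],
            int(t["frame"].iat[i]),
            float(d[i, j]),
        )
        for i, j in zip(ti, si)
    ]
    return sorted(rows)


@pytest.fixture
def config():
    return AnalysisConfig()
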