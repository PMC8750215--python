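"""Track–spot contact detection and episode merging.

A *contact* is a frame in which the Euclidean distance between a comet
center and a spot center falls strictly below ``radius + buffer`` — i.e.
the comet center comes within the configured allowance of the spot border.
Runs of contact frames of one (track, spot) pair merge into a single
*collision episode*, counted as one collision.

A compatibility criterion ``"diameter"`` compares the center distance to
the full spot diameter instead of ``radius + buffer``, reproducing the
original screening script's inequality.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, ValidationError
from .trackio import AnalysisConfig, SpotTable, TrackTable

__all__ = [
    "detect_contacts",
    "merge_episodes",
    "colliding_fractions",
    "CONTACT_COLUMNS",
    "EPISODE_COLUMNS",
]

CONTACT_COLUMNS = ["track_id", "spot_id", "frame", "center_distance", "border_distance"]
EPISODE_COLUMNS = [
    "track_id",
    "spot_id",
    "frame_start",
    "frame_end",
    "min_border_distance",
    "frame_at_min",
]


def _empty_contacts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": pd.Series(dtype=object),
            "spot_id": pd.Series(dtype=object),
            "frame": pd.Series(dtype=int),
            "center_distance": pd.Series(dtype=float),
            "border_distance": pd.Series(dtype=float),
        }
    )


def detect_contacts(
    tracks: TrackTable,
    spots: SpotTable,
    config: AnalysisConfig = AnalysisConfig(),
    criterion: str = "border",
) -> pd.DataFrame:
    """Per-frame track–spot contacts under the distance criterion.

    For every frame present in both tables, every (comet point, spot
    observation) pair with center distance ``d`` satisfying

    * ``criterion="border"``:  ``d < diameter/2 + config.buffer``
    * ``criterion="diameter"``:  ``d < diameter``

    is returned exactly once.  Ties at the threshold are non-contacts.
    Spots not observed in a frame contribute no contacts in that frame;
    spot positions are never interpolated.

    Returns a DataFrame with columns
    ``track_id, spot_id, frame, center_distance, border_distance`` where
    ``border_distance = center_distance - diameter/2``, sorted by
    (track_id, spot_id, frame).
    """
    if criterion not in ("border", "diameter"):
        raise ValueError(f"unknown criterion {criterion!r}")
    t = tracks.data
    s = spots.data
    common = np.intersect1d(t["frame"].unique(), s["frame"].unique())
    if len(common) == 0:
        warnings.warn("track and spot tables share no frames; no contacts")
        return _empty_contacts()

    t_by_frame = dict(tuple(t.groupby("frame", sort=True)))
    s_by_frame = dict(tuple(s.groupby("frame", sort=True)))
    chunks = []
    for frame in common:
        tf = t_by_frame[frame]
        sf = s_by_frame[frame]
        d = cdist(tf[["x", "y"]].to_numpy(float), sf[["x", "y"]].to_numpy(float))
        radius = sf["diameter"].to_numpy(float) / 2.0
        if criterion == "border":
            hit = d < radius[None, :] + config.buffer
        else:
            hit = d < 2.0 * radius[None, :]
        ti, si = np.nonzero(hit)
        if len(ti) == 0:
            continue
        chunks.append(
            pd.DataFrame(
                {
                    "track_id": tf["track_id"].to_numpy()[ti],
                    "spot_id": sf["spot_id"].to_numpy()[si],
                    "frame": int(frame),
                    "center_distance": d[ti, si],
                    "border_distance": d[ti, si] - radius[si],
                }
            )
        )
    if not chunks:
        return _empty_contacts()
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["track_id", "spot_id", "frame"]).reset_index(drop=True)


def merge_episodes(
    contacts: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Merge per-frame contacts into collision episodes.

    Contacts of one (track, spot) pair whose frames differ by at most
    ``config.episode_gap + 1`` belong to the same episode.  Each episode
    records its frame span, its minimal border distance and the frame at
    which that minimum occurs (first such frame on ties) — the *anchor
    frame* of the downstream kinetics.  Merging is idempotent and does not
    depend on input row order.
    """
    required = {"track_id", "spot_id", "frame", "border_distance"}
    missing = required - set(contacts.columns)
    if missing:
        raise ValidationError(f"contacts missing columns: {sorted(missing)}")
    if contacts.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    rows = []
    ordered = contacts.sort_values(["track_id", "spot_id", "frame"])
    for (track_id, spot_id), grp in ordered.groupby(["track_id", "spot_id"], sort=False):
        frames = grp["frame"].to_numpy(dtype=int)
        dists = grp["border_distance"].to_numpy(dtype=float)
        if len(np.unique(frames)) != len(frames):
            raise ValidationError(
                f"duplicate contact frames for pair ({track_id!r}, {spot_id!r})"
            )
        breaks = np.nonzero(np.diff(frames) > config.episode_gap + 1)[0] + 1
        for seg_f, seg_d in zip(np.split(frames, breaks), np.split(dists, breaks)):
            k = int(np.argmin(seg_d))
            rows.append(
                {
                    "track_id": track_id,
                    "spot_id": spot_id,
                    "frame_start": int(seg_f[0]),
                    "frame_end": int(seg_f[-1]),
                    "min_border_distance": float(seg_d[k]),
                    "frame_at_min": int(seg_f[k]),
                }
            )
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS)


def colliding_fractions(
    episodes: pd.DataFrame, tracks: TrackTable, spots: SpotTable
) -> Tuple[float, float]:
    """Percentage of tracks and of spots with at least one episode.

    Denominators are all tracks (resp. spots) present in the given tables;
    apply any track-length filter to ``tracks`` before calling.

    Returns ``(pct_tracks_colliding, pct_spots_colliding)`` in [0, 100].
    """
    n_tracks = tracks.n_tracks
    n_spots = spots.n_spots
    if n_tracks == 0 or n_spots == 0:
        raise EmptyInputError("cannot form percentages over an empty table")
    if episodes.empty:
        return 0.0, 0.0
    pct_tracks = 100.0 * episodes["track_id"].nunique() / n_tracks
    pct_spots = 100.0 * episodes["spot_id"].nunique() / n_spots
    return pct_tracks, pct_spots
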