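"""Track, spot, per-collision and per-cell statistics.

Definitions
-----------
* **path length** — sum of Euclidean step distances along a track (µm).
* **displacement** — straight-line distance from first to last point (µm).
* **straightness** — displacement / path length, in [0, 1]; 1 for a
  straight monotone track, 0 for a closed loop.
* **mean speed** — unweighted mean of per-step speeds (µm/s), matching the
  per-step "Speed" convention of tracking software.
* **near-collision speed** — mean step speed in a window of
  ``frames_before`` frames before to ``frames_after`` frames after the
  episode anchor frame (the frame of closest approach), clipped to the
  track's extent.
* **speed class** — a collision is *unaffected* when the near speed is
  within a relative tolerance of the whole-track mean speed, otherwise
  *accelerated* or *decelerated*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .collision import colliding_fractions, detect_contacts, merge_episodes
from .errors import (
    DegenerateTrackError,
    InsufficientWindowError,
    ValidationError,
)
from .trackio import AnalysisConfig, SpotTable, TrackTable

__all__ = [
    "step_speeds",
    "path_length",
    "displacement",
    "straightness",
    "track_metrics",
    "track_metrics_table",
    "near_collision_speed",
    "classify_collision",
    "straightness_change",
    "collision_kinetics",
    "spot_max_displacement",
    "spot_metrics_table",
    "summarize_cell",
    "analyze_cell",
    "CellSummary",
    "CellAnalysis",
]


def _xy(track: pd.DataFrame) -> np.ndarray:
    return track[["x", "y"]].to_numpy(dtype=float)


def _check_frames(track: pd.DataFrame) -> np.ndarray:
    frames = track["frame"].to_numpy(dtype=int)
    d = np.diff(frames)
    if np.any(d == 0):
        raise ValidationError("duplicate frames within a track")
    if np.any(d < 0):
        raise ValidationError("frames must be sorted increasing")
    return frames


def step_speeds(track: pd.DataFrame, frame_interval: float) -> np.ndarray:
    """Per-step speeds of one track in µm/s.

    ``speed_i = |p_{i+1} - p_i| / (Δframe_i · frame_interval)``; with
    consecutive frames this yields ``n_points - 1`` values.
    """
    if len(track) < 2:
        raise ValidationError("need at least 2 points for step speeds")
    frames = _check_frames(track)
    pos = _xy(track)
    dist = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return dist / (np.diff(frames) * frame_interval)


def path_length(track: pd.DataFrame) -> float:
    pos = _xy(track)
    return float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))


def displacement(track: pd.DataFrame) -> float:
    pos = _xy(track)
    return float(np.linalg.norm(pos[-1] - pos[0]))


def straightness(track: pd.DataFrame) -> float:
    """Displacement over path length; 0 for a degenerate (zero-length) path."""
    length = path_length(track)
    if length == 0.0:
        return 0.0
    return displacement(track) / length


@dataclass(frozen=True)
class TrackMetrics:
    track_id: object
    n_points: int
    length_um: float
    displacement_um: float
    straightness: float
    mean_speed_um_s: float
    n_collisions: int


def track_metrics(
    track: pd.DataFrame, frame_interval: float, n_collisions: int = 0
) -> TrackMetrics:
    """Whole-track statistics for a single track."""
    if len(track) < 2:
        raise ValidationError("track metrics need at least 2 points")
    speeds = step_speeds(track, frame_interval)
    length = path_length(track)
    disp = displacement(track)
    return TrackMetrics(
        track_id=track["track_id"].iloc[0] if "track_id" in track.columns else None,
        n_points=len(track),
        length_um=length,
        displacement_um=disp,
        straightness=(disp / length) if length > 0 else 0.0,
        mean_speed_um_s=float(np.mean(speeds)),
        n_collisions=int(n_collisions),
    )


def track_metrics_table(
    tracks: TrackTable, episodes: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Whole-track statistics for every track in the table."""
    counts = {}
    if episodes is not None and len(episodes):
        counts = episodes.groupby("track_id").size().to_dict()
    rows = []
    for tid in tracks.track_ids:
        m = track_metrics(tracks.track(tid), tracks.frame_interval, counts.get(tid, 0))
        rows.append(
            {
                "track_id": tid,
                "n_points": m.n_points,
                "length_um": m.length_um,
                "displacement_um": m.displacement_um,
                "straightness": m.straightness,
                "mean_speed_um_s": m.mean_speed_um_s,
                "n_collisions": m.n_collisions,
            }
        )
    return pd.DataFrame(rows)


def near_collision_speed(
    track: pd.DataFrame,
    episode,
    config: AnalysisConfig,
    frame_interval: float,
) -> float:
    """Mean step speed in the window around an episode's anchor frame.

    The window spans frames ``[anchor - frames_before, anchor +
    frames_after]`` (default −1/+3) and is clipped to the track's frame
    range; only steps lying fully inside the window count.
    """
    anchor = int(episode["frame_at_min"])
    lo = anchor - config.frames_before
    hi = anchor + config.frames_after
    frames = _check_frames(track)
    speeds = step_speeds(track, frame_interval)
    starts, ends = frames[:-1], frames[1:]
    mask = (starts >= lo) & (ends <= hi)
    if not mask.any():
        raise InsufficientWindowError(
            f"no steps in window [{lo}, {hi}] of track frames "
            f"[{frames[0]}, {frames[-1]}]"
        )
    return float(np.mean(speeds[mask]))


def classify_collision(
    near_speed: float, whole_track_speed: float, config: AnalysisConfig
) -> str:
    """Classify a collision as accelerated / decelerated / unaffected.

    Unaffected iff ``|near - whole| <= unaffected_rel_tol * whole``.
    """
    if whole_track_speed == 0:
        raise DegenerateTrackError("whole-track speed is zero")
    if abs(near_speed - whole_track_speed) <= config.unaffected_rel_tol * whole_track_speed:
        return "unaffected"
    return "accelerated" if near_speed > whole_track_speed else "decelerated"


def straightness_change(
    track: pd.DataFrame, episode
) -> Tuple[Optional[float], Optional[float], Optional[bool]]:
    """Straightness before and after the anchor frame.

    The *before* sub-track runs up to and including the anchor frame, the
    *after* sub-track from the anchor frame onward.  A side with fewer than
    2 points is undefined and reported as ``None``.
    ``straightness_decreased`` compares the after-side straightness with the
    whole track's and is ``None`` when the after side is undefined.
    """
    anchor = int(episode["frame_at_min"])
    before = track[track["frame"] <= anchor]
    after = track[track["frame"] >= anchor]
    s_before = straightness(before) if len(before) >= 2 else None
    s_after = straightness(after) if len(after) >= 2 else None
    if s_after is None:
        decreased = None
    else:
        decreased = bool(s_after < straightness(track))
    return s_before, s_after, decreased


def collision_kinetics(
    tracks: TrackTable, episodes: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Per-episode kinetics: near speed, class, straightness change.

    Episodes whose window holds no step (e.g. at the very end of a short
    track) are kept with ``valid = False`` and NaN kinetics rather than
    aborting the batch.
    """
    rows = []
    # to_dict preserves per-column dtypes (iterrows would upcast ids to float)
    for ep in episodes.to_dict("records"):
        track = tracks.track(ep["track_id"])
        whole = float(np.mean(step_speeds(track, tracks.frame_interval)))
        row = {
            "track_id": ep["track_id"],
            "spot_id": ep["spot_id"],
            "frame_at_min": int(ep["frame_at_min"]),
            "min_border_distance": float(ep["min_border_distance"]),
            "whole_track_speed": whole,
            "near_speed": np.nan,
            "speed_class": None,
            "straightness_before": np.nan,
            "straightness_after": np.nan,
            "straightness_decreased": None,
            "valid": False,
        }
        try:
            near = near_collision_speed(track, ep, config, tracks.frame_interval)
            row["near_speed"] = near
            row["speed_class"] = classify_collision(near, whole, config)
            row["valid"] = True
        except (InsufficientWindowError, DegenerateTrackError):
            pass
        s_before, s_after, decreased = straightness_change(track, ep)
        row["straightness_before"] = np.nan if s_before is None else s_before
        row["straightness_after"] = np.nan if s_after is None else s_after
        row["straightness_decreased"] = decreased
        rows.append(row)
    columns = [
        "track_id",
        "spot_id",
        "frame_at_min",
        "min_border_distance",
        "whole_track_speed",
        "near_speed",
        "speed_class",
        "straightness_before",
        "straightness_after",
        "straightness_decreased",
        "valid",
    ]
    return pd.DataFrame(rows, columns=columns)


def spot_max_displacement(spot: pd.DataFrame) -> float:
    """Maximal distance of a spot from its first observed position (µm)."""
    if len(spot) == 0:
        raise ValidationError("spot has no observations")
    pos = _xy(spot)
    return float(np.max(np.linalg.norm(pos - pos[0], axis=1)))


def spot_metrics_table(
    spots: SpotTable, episodes: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    counts = {}
    if episodes is not None and len(episodes):
        counts = episodes.groupby("spot_id").size().to_dict()
    rows = []
    for sid in spots.spot_ids:
        s = spots.spot(sid)
        rows.append(
            {
                "spot_id": sid,
                "n_frames": len(s),
                "max_displacement_um": spot_max_displacement(s),
                "n_collisions": counts.get(sid, 0),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CellSummary:
    """Per-cell collision frequencies, all as percentages.

    ``pct_acc/pct_dec/pct_unaffected`` are over *colliding* tracks (each
    track counted once by the majority class of its episodes) and sum to
    100 when at least one colliding track is classifiable.
    ``pct_acc_str_loss`` is the percent of colliding tracks that are
    accelerated and whose representative episode lost straightness.
    ``no_colliding_tracks`` flags the degenerate case where the class
    percentages are reported as 0.
    """

    pct_spots_colliding: float
    pct_tracks_colliding: float
    pct_acc: float
    pct_dec: float
    pct_unaffected: float
    pct_acc_str_loss: float
    no_colliding_tracks: bool = False


def _track_class(group: pd.DataFrame) -> Tuple[Optional[str], Optional[bool]]:
    """Majority speed class of one track's episodes.

    Ties break to the class of the episode with the smallest minimal border
    distance.  Returns (class, straightness_decreased of the representative
    episode: the closest-approach episode within the winning class).
    """
    valid = group[group["valid"] & group["speed_class"].notna()]
    if valid.empty:
        return None, None
    counts = valid["speed_class"].value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        winner = top[0]
    else:
        tied = valid[valid["speed_class"].isin(top)]
        winner = tied.loc[tied["min_border_distance"].idxmin(), "speed_class"]
    within = valid[valid["speed_class"] == winner]
    rep = within.loc[within["min_border_distance"].idxmin()]
    return winner, rep["straightness_decreased"]


def summarize_cell(
    track_metrics: pd.DataFrame,
    kinetics: pd.DataFrame,
    tracks: TrackTable,
    spots: SpotTable,
    config: AnalysisConfig,
) -> CellSummary:
    """Collision frequencies of one cell (one field of view)."""
    episodes_like = kinetics if len(kinetics) else pd.DataFrame(columns=["track_id", "spot_id"])
    pct_tracks, pct_spots = colliding_fractions(episodes_like, tracks, spots)
    if kinetics.empty:
        return CellSummary(pct_spots, pct_tracks, 0.0, 0.0, 0.0, 0.0, True)
    classes = {}
    str_loss = {}
    for tid, grp in kinetics.groupby("track_id"):
        cls, dec = _track_class(grp)
        if cls is not None:
            classes[tid] = cls
            str_loss[tid] = dec
    n = len(classes)
    if n == 0:
        return CellSummary(pct_spots, pct_tracks, 0.0, 0.0, 0.0, 0.0, True)
    vals = list(classes.values())
    pct_acc = 100.0 * vals.count("accelerated") / n
    pct_dec = 100.0 * vals.count("decelerated") / n
    pct_un = 100.0 * vals.count("unaffected") / n
    n_acc_loss = sum(
        1
        for tid, cls in classes.items()
        if cls == "accelerated" and str_loss.get(tid) is True
    )
    return CellSummary(
        pct_spots_colliding=pct_spots,
        pct_tracks_colliding=pct_tracks,
        pct_acc=pct_acc,
        pct_dec=pct_dec,
        pct_unaffected=pct_un,
        pct_acc_str_loss=100.0 * n_acc_loss / n,
    )


@dataclass
class CellAnalysis:
    """Bundle of all per-cell outputs of :func:`analyze_cell`."""

    contacts: pd.DataFrame
    episodes: pd.DataFrame
    track_metrics: pd.DataFrame
    spot_metrics: pd.DataFrame
    kinetics: pd.DataFrame
    summary: CellSummary
    tracks: TrackTable  # tracks actually analyzed (after length filter)


def analyze_cell(
    tracks: TrackTable,
    spots: SpotTable,
    config: AnalysisConfig = AnalysisConfig(),
    criterion: str = "border",
    apply_min_length: bool = True,
) -> CellAnalysis:
    """Full per-cell pipeline: detect, merge, measure, summarize.

    With ``apply_min_length`` (the per-cell convention) only tracks whose
    path length strictly exceeds ``config.min_track_length`` are followed;
    detection, metrics and all percentages then refer to those tracks.
    """
    if apply_min_length and config.min_track_length > 0:
        lengths = {tid: path_length(tracks.track(tid)) for tid in tracks.track_ids}
        keep = [tid for tid, L in lengths.items() if L > config.min_track_length]
        if keep:
            tracks = tracks.subset(keep)
        else:
            raise ValidationError(
                f"no tracks longer than {config.min_track_length} µm"
            )
    contacts = detect_contacts(tracks, spots, config, criterion=criterion)
    episodes = merge_episodes(contacts, config)
    kinetics = collision_kinetics(tracks, episodes, config)
    tm = track_metrics_table(tracks, episodes)
    classes = {}
    for tid, grp in kinetics.groupby("track_id"):
        cls, _ = _track_class(grp)
        classes[tid] = cls
    tm["class"] = tm["track_id"].map(lambda t: classes.get(t) or "none")
    sm = spot_metrics_table(spots, episodes)
    summary = summarize_cell(tm, kinetics, tracks, spots, config)
    return CellAnalysis(contacts, episodes, tm, sm, kinetics, summary, tracks)
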