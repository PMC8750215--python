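"""Synthetic tracks, spots and fiber images with known ground truth.

The generator emulates the three data sources of the analysis:

* **Comet tracks** — persistent random walks: each track has a constant
  intrinsic speed drawn once per track, a heading that evolves by
  wrapped-normal increments per step (lateral waviness of the growing
  tip), and starts uniformly in a square field.  Defaults emulate EB1
  comets in leaf epidermal cells: 0.266 ± 0.152 µm/s, 50 frames at 1 s.
* **Membrane spots** — near-immobile clusters: a fixed anchor with
  independent Gaussian jitter per frame (not a random walk, so the maximal
  displacement stays bounded, at the ~0.18 µm scale observed for membrane
  clusters) and a per-spot diameter.
* **Fiber images** — anti-aliased straight lines with angles drawn from a
  wrapped normal distribution, for testing orientation-dispersion
  estimation.

Collisions are *planted*: a spot is centered on a chosen track position and
the track is modified from that frame on according to one of four
outcomes — ``pass`` (continues, optionally re-scaled in speed), ``pause``
(comet stalls then disappears: the track is truncated), ``detach_turn``
(heading change plus transient extra waviness), ``retract`` (the tip
retraces its path backward).  Every generator is reproducible from its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trackio import AnalysisConfig, SpotTable, TrackTable

__all__ = [
    "TrackSimParams",
    "SpotSimParams",
    "PlannedCollision",
    "simulate_tracks",
    "plant_collisions",
    "render_fiber_image",
]


@dataclass(frozen=True)
class TrackSimParams:
    """Parameters of the comet-track simulator.

    ``speed_mean``/``speed_sd`` are µm/s (negative draws are rejected),
    ``turn_sd`` is the per-step heading change in degrees, ``field_size``
    the side of the square start area in µm.
    """

    n_tracks: int = 30
    n_frames: int = 50
    frame_interval: float = 1.0
    speed_mean: float = 0.266
    speed_sd: float = 0.152
    turn_sd: float = 15.0
    field_size: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks <= 0 or self.n_frames < 2:
            raise ValidationError("need n_tracks > 0 and n_frames >= 2")
        if self.frame_interval <= 0 or self.field_size <= 0:
            raise ValidationError("frame_interval and field_size must be > 0")
        if self.speed_mean <= 0 or self.speed_sd < 0 or self.turn_sd < 0:
            raise ValidationError("speed_mean > 0, speed_sd/turn_sd >= 0 required")


@dataclass(frozen=True)
class SpotSimParams:
    """Parameters of the membrane-spot simulator.

    ``jitter_sd`` is the per-frame isotropic Gaussian jitter around the
    anchor (µm); keep it small relative to the diameter.
    """

    n_spots: int = 20
    diameter_mean: float = 0.5
    diameter_sd: float = 0.1
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise ValidationError("n_spots must be >= 0")
        if self.diameter_mean <= 0 or self.diameter_sd < 0 or self.jitter_sd < 0:
            raise ValidationError("diameter_mean > 0 and sds >= 0 required")


@dataclass(frozen=True)
class PlannedCollision:
    """One planted collision on a simulated track."""

    track_id: int
    frame: int
    outcome: str = "pass"  # pass | pause | detach_turn | retract
    speed_factor: float = 1.0
    turn_angle: float = 0.0  # degrees, detach_turn only
    pause_frames: int = 3  # pause only: frames held before truncation

    def __post_init__(self) -> None:
        if self.outcome not in ("pass", "pause", "detach_turn", "retract"):
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.speed_factor < 0:
            raise ValidationError("speed_factor must be >= 0")


def simulate_tracks(params: TrackSimParams) -> Tuple[TrackTable, pd.DataFrame]:
    """Simulate persistent comet tracks.

    Returns the :class:`TrackTable` and a per-track ground-truth frame
    (``track_id, speed, heading0``).  Identical params (including seed)
    produce identical tables.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    truth = []
    for tid in range(params.n_tracks):
        if params.speed_sd == 0:
            speed = params.speed_mean
        else:
            speed = -1.0
            while speed <= 0:
                speed = rng.normal(params.speed_mean, params.speed_sd)
        heading0 = rng.uniform(-np.pi, np.pi)
        start = rng.uniform(0, params.field_size, size=2)
        turns = rng.normal(0.0, np.deg2rad(params.turn_sd), size=params.n_frames - 1)
        headings = heading0 + np.concatenate([[0.0], np.cumsum(turns[:-1])]) \
            if params.n_frames > 2 else np.array([heading0])
        step = speed * params.frame_interval
        dx = step * np.cos(headings)
        dy = step * np.sin(headings)
        x = start[0] + np.concatenate([[0.0], np.cumsum(dx)])
        y = start[1] + np.concatenate([[0.0], np.cumsum(dy)])
        for f in range(params.n_frames):
            rows.append((tid, f, x[f], y[f]))
        truth.append({"track_id": tid, "speed": speed, "heading0": heading0})
    data = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    return TrackTable(data, frame_interval=params.frame_interval), pd.DataFrame(truth)


def _rot(v: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v @ np.array([[c, s], [-s, c]]).T


def _apply_outcome(
    pos: np.ndarray, plan: PlannedCollision, turn_sd_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Rewrite a track's positions from the planted frame per the outcome."""
    k = plan.frame
    v = np.diff(pos, axis=0)  # v[i] = step from frame i to i+1
    if plan.outcome == "pause":
        held = np.repeat(pos[k][None, :], plan.pause_frames, axis=0)
        return np.vstack([pos[: k + 1], held])
    if plan.outcome == "retract":
        n_back = min(len(v) - k, k)
        back = -v[k - n_back : k][::-1] * plan.speed_factor
        out = [pos[: k + 1]]
        if n_back:
            out.append(pos[k] + np.cumsum(back, axis=0))
        return np.vstack(out)
    after = v[k:].copy() * plan.speed_factor
    if plan.outcome == "detach_turn":
        after = _rot(after, np.deg2rad(plan.turn_angle))
        extra = rng.normal(0.0, np.deg2rad(2.0 * max(turn_sd_deg, 1.0)), size=len(after))
        after = np.array([_rot(a, e) for a, e in zip(after, np.cumsum(extra))])
    return np.vstack([pos[: k + 1], pos[k] + np.cumsum(after, axis=0)])


def _place_background_spots(
    rng: np.random.Generator,
    n: int,
    track_pos: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    diameters: np.ndarray,
    clearance: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Anchors at least ``diameter/2 + clearance`` from every track point."""
    anchors = []
    tries = 0
    i = 0
    while i < n:
        if tries >= max_tries:
            raise ValidationError(
                "could not place background spots away from all tracks; "
                "reduce n_spots or the clearance"
            )
        cand = rng.uniform(lo, hi)
        tries += 1
        dmin = np.min(np.linalg.norm(track_pos - cand, axis=1)) if len(track_pos) else np.inf
        if dmin >= diameters[i] / 2.0 + clearance:
            anchors.append(cand)
            i += 1
    return np.asarray(anchors)


def plant_collisions(
    tracks: TrackTable,
    spot_params: SpotSimParams,
    plan: Sequence[PlannedCollision] = (),
    config: AnalysisConfig = AnalysisConfig(),
    turn_sd: float = 8.0,
) -> Tuple[TrackTable, SpotTable, pd.DataFrame]:
    """Plant collisions on simulated tracks and build the spot field.

    One spot is anchored exactly on the track position at each planted
    frame and the track is modified from that frame per the plan's outcome.
    Remaining spots (up to ``spot_params.n_spots``) are placed as
    background, kept at least ``diameter/2 + buffer + 3·jitter_sd + 0.05``
    µm away from every track point so they can never register a contact.
    With an empty plan all spots are background and the detector must find
    zero contacts.

    Returns the modified tracks, the spots, and the planted ground-truth
    episodes (``track_id, spot_id, frame``).
    """
    rng = np.random.default_rng(spot_params.seed)
    window = config.frames_before + config.frames_after
    by_track: dict = {}
    for p in plan:
        by_track.setdefault(p.track_id, []).append(p)
    for tid, plants in by_track.items():
        plants.sort(key=lambda p: p.frame)
        frames = [p.frame for p in plants]
        if any(b - a <= window for a, b in zip(frames, frames[1:])):
            raise ValidationError(
                f"planted frames on track {tid} closer than the ±window"
            )

    n_frames_max = int(tracks.data["frame"].max()) + 1
    new_rows = []
    anchors: List[np.ndarray] = []
    planted = []
    spot_idx = 0
    for tid in tracks.track_ids:
        t = tracks.track(tid)
        frames = t["frame"].to_numpy(int)
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise ValidationError("plant_collisions requires gap-free tracks")
        pos = t[["x", "y"]].to_numpy(float)
        for p in sorted(by_track.get(tid, []), key=lambda q: q.frame):
            k = p.frame - frames[0]
            if not 0 < k < len(pos) - 1:
                raise ValidationError(
                    f"planted frame {p.frame} outside interior of track {tid}"
                )
            anchors.append(pos[k].copy())
            planted.append({"track_id": tid, "spot_id": spot_idx, "frame": p.frame})
            spot_idx += 1
            pos = _apply_outcome(pos, PlannedCollision(
                p.track_id, k, p.outcome, p.speed_factor, p.turn_angle, p.pause_frames
            ), turn_sd, rng)
        for i, xy in enumerate(pos):
            new_rows.append((tid, frames[0] + i, xy[0], xy[1]))

    new_data = pd.DataFrame(new_rows, columns=["track_id", "frame", "x", "y"])
    new_tracks = TrackTable(new_data, frame_interval=tracks.frame_interval)

    n_background = max(spot_params.n_spots - len(anchors), 0)
    diam_all = np.maximum(
        rng.normal(spot_params.diameter_mean, spot_params.diameter_sd,
                   size=len(anchors) + n_background),
        0.1,
    )
    if n_background:
        track_pos = new_tracks.data[["x", "y"]].to_numpy(float)
        lo = track_pos.min(axis=0) - 2.0
        hi = track_pos.max(axis=0) + 2.0
        clearance = config.buffer + 3.0 * spot_params.jitter_sd + 0.05
        bg = _place_background_spots(
            rng, n_background, track_pos, lo, hi, diam_all[len(anchors):], clearance
        )
        anchors = anchors + list(bg)

    spot_rows = []
    for sid, anchor in enumerate(anchors):
        jitter = (
            rng.normal(0.0, spot_params.jitter_sd, size=(n_frames_max, 2))
            if spot_params.jitter_sd > 0
            else np.zeros((n_frames_max, 2))
        )
        for f in range(n_frames_max):
            spot_rows.append(
                (sid, f, anchor[0] + jitter[f, 0], anchor[1] + jitter[f, 1], diam_all[sid])
            )
    spot_data = pd.DataFrame(
        spot_rows, columns=["spot_id", "frame", "x", "y", "diameter"]
    )
    spots = SpotTable(spot_data, frame_interval=tracks.frame_interval)
    planted_df = pd.DataFrame(planted, columns=["track_id", "spot_id", "frame"])
    return new_tracks, spots, planted_df


def render_fiber_image(
    width: int = 512,
    height: int = 512,
    n_fibers: int = 60,
    angle_mean: float = 0.0,
    angle_sd: float = 10.0,
    line_width_px: int = 2,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render straight fibers with a controlled orientation distribution.

    Angles are drawn from a wrapped normal (degrees, period 180°) around
    ``angle_mean``; each fiber is an anti-aliased straight segment of
    length 0.6·min(width, height) through a random interior point, drawn
    ``line_width_px`` pixels wide.  Additive Gaussian noise of sd
    ``noise_sd`` is applied and the image clipped to [0, 1].

    The fiber angle is measured from the image x-axis (columns) toward the
    y-axis (rows), matching the convention of the orientation histogram.

    Returns (image float64 HxW in [0, 1], drawn angles in degrees).
    """
    from skimage.draw import line_aa

    if width < 16 or height < 16:
        raise ValidationError("image must be at least 16x16")
    if n_fibers <= 0 or line_width_px < 1:
        raise ValidationError("n_fibers and line_width_px must be >= 1")
    rng = np.random.default_rng(seed)
    angles = angle_mean + angle_sd * rng.standard_normal(n_fibers)
    angles = (angles + 90.0) % 180.0 - 90.0
    img = np.zeros((height, width), dtype=float)
    half = 0.3 * min(width, height)
    for theta in angles:
        rad = np.deg2rad(theta)
        d = np.array([np.sin(rad), np.cos(rad)])  # (row, col) direction
        n = np.array([-d[1], d[0]])  # unit normal for line thickness
        center = rng.uniform([0.2 * height, 0.2 * width], [0.8 * height, 0.8 * width])
        for off in np.arange(line_width_px) - (line_width_px - 1) / 2.0:
            a = center + half * d + off * n
            b = center - half * d + off * n
            rr, cc, val = line_aa(
                int(round(a[0])), int(round(a[1])), int(round(b[0])), int(round(b[1]))
            )
            keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
            img[rr[keep], cc[keep]] = np.maximum(img[rr[keep], cc[keep]], val[keep])
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), angles
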