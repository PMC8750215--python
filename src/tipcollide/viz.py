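"""Per-frame rendering and animation of tracks, spots and collisions.

Tracks are drawn as growing polylines, spots as circles at their stated
diameter.  A track or spot switches to the "collided" color (white by
default) at the first frame of its first collision episode and keeps it
for the rest of the movie; one track may be highlighted in a distinct
color and width.  Annotations (scale bar) are drawn in gray so that pure
white is reserved for collided elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import FormatError
from .trackio import SpotTable, TrackTable

__all__ = ["RenderStyle", "render_frames", "render_animation"]


@dataclass(frozen=True)
class RenderStyle:
    track_color: str = "yellow"
    collided_track_color: str = "white"
    spot_color: str = "red"
    collided_spot_color: str = "white"
    selected_track_id: Optional[object] = None
    selected_color: str = "deepskyblue"
    selected_width: float = 2.5
    track_width: float = 1.0
    background: str = "black"

    def __post_init__(self) -> None:
        if self.track_width <= 0 or self.selected_width <= 0:
            raise ValueError("line widths must be > 0")


def _first_episode_frames(episodes: pd.DataFrame, key: str) -> dict:
    if episodes is None or len(episodes) == 0:
        return {}
    return episodes.groupby(key)["frame_start"].min().to_dict()


def render_frames(
    tracks: TrackTable,
    spots: SpotTable,
    episodes: Optional[pd.DataFrame] = None,
    style: RenderStyle = RenderStyle(),
    width_px: int = 480,
) -> List[np.ndarray]:
    """Render one RGB frame (uint8 HxWx3) per time point.

    The world-to-pixel scale is fixed by the bounding box of all tracks
    and spots plus a 5% margin; a 1 µm scale bar is drawn.  Rendering is
    deterministic for fixed inputs.
    """
    t = tracks.data
    s = spots.data
    frames = sorted(set(t["frame"].astype(int)) | set(s["frame"].astype(int)))
    track_white = _first_episode_frames(episodes, "track_id")
    spot_white = _first_episode_frames(episodes, "spot_id")

    r = s["diameter"].to_numpy(float) / 2.0
    xs = np.concatenate([t["x"].to_numpy(float), s["x"].to_numpy(float) - r,
                         s["x"].to_numpy(float) + r])
    ys = np.concatenate([t["y"].to_numpy(float), s["y"].to_numpy(float) - r,
                         s["y"].to_numpy(float) + r])
    margin_x = 0.05 * max(np.ptp(xs), 1e-6)
    margin_y = 0.05 * max(np.ptp(ys), 1e-6)
    xlim = (xs.min() - margin_x, xs.max() + margin_x)
    ylim = (ys.min() - margin_y, ys.max() + margin_y)
    aspect = (ylim[1] - ylim[0]) / (xlim[1] - xlim[0])
    height_px = max(int(round(width_px * aspect)), 64)

    track_pts = {tid: tracks.track(tid) for tid in tracks.track_ids}
    spot_by_frame = dict(tuple(s.groupby("frame")))

    dpi = 100
    fig, ax = plt.subplots(
        figsize=(width_px / dpi, height_px / dpi), dpi=dpi, facecolor=style.background
    )
    out: List[np.ndarray] = []
    try:
        for frame in frames:
            ax.clear()
            ax.set_facecolor(style.background)
            ax.set_xlim(*xlim)
            ax.set_ylim(*ylim)
            ax.set_aspect("equal")
            ax.axis("off")
            for sid_frame in ([frame] if frame in spot_by_frame else []):
                sf = spot_by_frame[sid_frame]
                for _, row in sf.iterrows():
                    collided = spot_white.get(row["spot_id"], np.inf) <= frame
                    color = style.collided_spot_color if collided else style.spot_color
                    ax.add_patch(
                        plt.Circle(
                            (row["x"], row["y"]),
                            row["diameter"] / 2.0,
                            fill=False,
                            edgecolor=color,
                            linewidth=1.2,
                        )
                    )
            for tid, pts in track_pts.items():
                seen = pts[pts["frame"] <= frame]
                if len(seen) < 2:
                    continue
                if tid == style.selected_track_id:
                    color, lw = style.selected_color, style.selected_width
                elif track_white.get(tid, np.inf) <= frame:
                    color, lw = style.collided_track_color, style.track_width
                else:
                    color, lw = style.track_color, style.track_width
                ax.plot(seen["x"], seen["y"], color=color, linewidth=lw,
                        solid_capstyle="round")
            # 1 µm scale bar, bottom left, gray (white is reserved)
            x0 = xlim[0] + 0.05 * (xlim[1] - xlim[0])
            y0 = ylim[0] + 0.05 * (ylim[1] - ylim[0])
            ax.plot([x0, x0 + 1.0], [y0, y0], color="0.5", linewidth=2.0)
            fig.subplots_adjust(left=0, right=1, top=1, bottom=0)
            fig.canvas.draw()
            buf = np.asarray(fig.canvas.buffer_rgba())[:, :, :3]
            out.append(buf.copy())
    finally:
        plt.close(fig)
    return out


def render_animation(
    tracks: TrackTable,
    spots: SpotTable,
    episodes: Optional[pd.DataFrame],
    path: Union[str, Path],
    style: RenderStyle = RenderStyle(),
    fps: float = 5.0,
    width_px: int = 480,
) -> Path:
    """Render and save the collision animation as GIF or MP4.

    The output format follows the file extension (``.gif`` or ``.mp4``;
    MP4 requires an ffmpeg-enabled imageio plugin).
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in (".gif", ".mp4"):
        raise FormatError(f"unsupported animation format {ext!r}; use .gif or .mp4")
    frames = render_frames(tracks, spots, episodes, style=style, width_px=width_px)
    import imageio.v2 as iio

    if ext == ".gif":
        iio.mimsave(path, frames, duration=1.0 / fps, loop=0)
    else:
        iio.mimsave(path, frames, fps=fps)
    return path
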