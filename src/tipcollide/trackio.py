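"""Tracking-table I/O and shared domain types.

Two table kinds flow through the package:

* **tracks** — time-ordered positions of moving EB1 comets (growing
  microtubule plus-ends), grouped by track id.
* **spots** — per-frame positions *and diameters* of near-immobile
  membrane-associated clusters, grouped by spot id.

Both are stored internally as a tidy :class:`pandas.DataFrame` wrapped in a
light container that also carries the acquisition frame interval.  Positions
are always in micrometres and frames are 0-based integers.

Two on-disk dialects are supported:

* ``canonical`` — flat CSV with columns ``id, frame, x_um, y_um`` (tracks)
  plus ``diameter_um`` (spots); optional ``z_um`` is carried but ignored by
  the planar analysis.
* ``imaris`` — the statistics-export dialect of the Imaris tracking
  software: columns ``Position X/Y/Z``, ``Unit``, ``Time`` (1-based frame
  index), ``TrackID``, ``ID``.  Diameters live in a separate statistics
  file joined on the per-object ``ID``; alternatively a constant fallback
  diameter may be supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError, ValidationError

__all__ = [
    "AnalysisConfig",
    "TrackTable",
    "SpotTable",
    "read_table",
    "read_tracks",
    "read_spots",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

# Unit column values accepted in Imaris exports, mapped to µm multipliers.
_UNIT_TO_UM = {
    "um": 1.0,
    "µm": 1.0,
    "μm": 1.0,
    "micrometer": 1.0,
    "micrometers": 1.0,
    "nm": 1e-3,
    "mm": 1e3,
    "m": 1e6,
}

TRACK_COLUMNS = ["track_id", "frame", "x", "y"]
SPOT_COLUMNS = ["spot_id", "frame", "x", "y", "diameter"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows of the collision analysis.

    Parameters
    ----------
    buffer:
        Distance allowance in µm beyond the spot border: a comet center
        within ``radius + buffer`` of a spot center is in contact.
        Default 0.1 µm (100 nm).
    frames_before, frames_after:
        Near-collision speed window, in frames relative to the collision
        anchor frame (the frame of closest approach).  Defaults 1 and 3.
    min_track_length:
        Path-length filter in µm applied before per-cell summaries; only
        tracks strictly longer than this are followed.  Default 5 µm.
    unaffected_rel_tol:
        Relative tolerance for calling a collision speed "unaffected":
        ``|near - whole| <= tol * whole``.  Default 0.05.
    episode_gap:
        Number of missing frames tolerated inside one collision episode.
        Default 0 (only consecutive contact frames merge).
    """

    buffer: float = 0.1
    frames_before: int = 1
    frames_after: int = 3
    min_track_length: float = 5.0
    unaffected_rel_tol: float = 0.05
    episode_gap: int = 0

    def __post_init__(self) -> None:
        if self.buffer < 0:
            raise ValidationError("buffer must be >= 0")
        if self.frames_before < 0 or self.frames_after < 0:
            raise ValidationError("window frame counts must be >= 0")
        if self.min_track_length < 0:
            raise ValidationError("min_track_length must be >= 0")
        if not 0 <= self.unaffected_rel_tol < 1:
            raise ValidationError("unaffected_rel_tol must be in [0, 1)")
        if self.episode_gap < 0:
            raise ValidationError("episode_gap must be >= 0")


def _validate_points(df: pd.DataFrame, id_col: str, what: str) -> None:
    for col in ("x", "y"):
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"non-finite {col} position in {what} table")
    for key, grp in df.groupby(id_col, sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValidationError(
                f"frames not strictly increasing within {what} {key!r}"
            )


@dataclass
class TrackTable:
    """Time-ordered comet positions grouped by track id.

    ``data`` columns: ``track_id, frame, x, y`` (optional ``z``), sorted by
    (track_id, frame).  ``frame_interval`` is in seconds per frame.
    """

    data: pd.DataFrame
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"track table missing columns: {missing}")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        self.data = self.data.sort_values(["track_id", "frame"]).reset_index(drop=True)
        _validate_points(self.data, "track_id", "track")
        sizes = self.data.groupby("track_id", sort=False).size()
        short = sizes[sizes < 2]
        if len(short):
            raise ValidationError(
                f"tracks with fewer than 2 points: {list(short.index)}"
            )

    @property
    def track_ids(self) -> list:
        return list(self.data["track_id"].unique())

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def track(self, track_id) -> pd.DataFrame:
        """Points of one track, sorted by frame."""
        out = self.data[self.data["track_id"] == track_id]
        if out.empty:
            raise KeyError(track_id)
        return out.reset_index(drop=True)

    def subset(self, track_ids: Iterable) -> "TrackTable":
        keep = set(track_ids)
        return TrackTable(
            self.data[self.data["track_id"].isin(keep)].copy(), self.frame_interval
        )


@dataclass
class SpotTable:
    """Per-frame positions and diameters of membrane clusters.

    ``data`` columns: ``spot_id, frame, x, y, diameter`` (µm).
    """

    data: pd.DataFrame
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"spot table missing columns: {missing}")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        self.data = self.data.sort_values(["spot_id", "frame"]).reset_index(drop=True)
        _validate_points(self.data, "spot_id", "spot")
        if (self.data["diameter"].to_numpy(dtype=float) <= 0).any():
            raise ValidationError("spot diameters must be > 0")

    @property
    def spot_ids(self) -> list:
        return list(self.data["spot_id"].unique())

    @property
    def n_spots(self) -> int:
        return self.data["spot_id"].nunique()

    def spot(self, spot_id) -> pd.DataFrame:
        out = self.data[self.data["spot_id"] == spot_id]
        if out.empty:
            raise KeyError(spot_id)
        return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_IMARIS_REQUIRED = ["Position X", "Position Y", "Position Z", "Unit", "Time", "TrackID", "ID"]


def _read_csv_any_header(path: Union[str, Path], marker: str) -> pd.DataFrame:
    """Read a CSV whose column-header row may be preceded by title lines.

    Imaris statistic exports carry up to three banner lines before the
    header; the row containing *marker* is taken as the header.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8-sig") as fh:
        head = [fh.readline() for _ in range(8)]
    skip = 0
    # The header row must actually be delimited; banner lines repeating the
    # statistic name ("Diameter") alone are skipped.
    for i, line in enumerate(head):
        if marker in line and "," in line:
            skip = i
            break
    return pd.read_csv(path, skiprows=skip, encoding="utf-8-sig")


def _unit_factor(unit) -> float:
    key = str(unit).strip().lower()
    if key not in _UNIT_TO_UM:
        raise SchemaError(f"unknown length unit {unit!r}")
    return _UNIT_TO_UM[key]


def _read_imaris_positions(position_file: Union[str, Path]) -> pd.DataFrame:
    df = _read_csv_any_header(position_file, "Position X")
    df.columns = [str(c).strip() for c in df.columns]
    for col in _IMARIS_REQUIRED:
        if col not in df.columns:
            raise SchemaError(col)
    if df.empty:
        raise EmptyInputError(f"{position_file} contains no data rows")
    factors = df["Unit"].map(_unit_factor).to_numpy()
    out = pd.DataFrame(
        {
            "object_id": df["ID"].to_numpy(),
            "track_id": df["TrackID"].to_numpy(),
            # Imaris Time is a 1-based frame index
            "frame": df["Time"].to_numpy(dtype=int) - 1,
            "x": df["Position X"].to_numpy(dtype=float) * factors,
            "y": df["Position Y"].to_numpy(dtype=float) * factors,
            "z": df["Position Z"].to_numpy(dtype=float) * factors,
        }
    )
    return out


def _read_imaris_diameters(diameter_file: Union[str, Path]) -> pd.Series:
    df = _read_csv_any_header(diameter_file, "Diameter")
    df.columns = [str(c).strip() for c in df.columns]
    diam_col = next((c for c in ("Diameter X", "Diameter") if c in df.columns), None)
    if diam_col is None:
        raise SchemaError("Diameter")
    if "ID" not in df.columns:
        raise SchemaError("ID")
    vals = df[diam_col].to_numpy(dtype=float)
    if "Unit" in df.columns:
        vals = vals * df["Unit"].map(_unit_factor).to_numpy()
    return pd.Series(vals, index=df["ID"].to_numpy())


def read_table(
    position_file: Union[str, Path],
    *,
    kind: str = "tracks",
    dialect: str = "canonical",
    diameter_file: Optional[Union[str, Path]] = None,
    default_diameter: Optional[float] = None,
    frame_interval: float = 1.0,
) -> Union[TrackTable, SpotTable]:
    """Read a track or spot table from CSV.

    Parameters
    ----------
    kind:
        ``"tracks"`` or ``"spots"``.
    dialect:
        ``"canonical"`` or ``"imaris"`` (see module docstring).
    diameter_file:
        Imaris dialect, spots only: separate diameter statistics file,
        joined on the per-object ``ID``.
    default_diameter:
        Constant diameter in µm used when no diameter column/file is given.
    frame_interval:
        Seconds per frame of the acquisition.

    Returns
    -------
    TrackTable or SpotTable
    """
    if kind not in ("tracks", "spots"):
        raise ValueError(f"kind must be 'tracks' or 'spots', got {kind!r}")
    if dialect == "imaris":
        pos = _read_imaris_positions(position_file)
        # Spots from the Spot Creation Wizard are tracked over time too;
        # the spot identity is its TrackID, the per-frame object its ID.
        pos = pos.rename(columns={"track_id": "id"})
        if kind == "spots":
            if diameter_file is not None:
                diam = _read_imaris_diameters(diameter_file)
                mapped = pos["object_id"].map(diam)
                if mapped.isna().any():
                    missing = pos.loc[mapped.isna(), "object_id"].tolist()[:5]
                    raise ValidationError(
                        f"diameter file lacks object IDs, e.g. {missing}"
                    )
                pos["diameter"] = mapped.to_numpy(dtype=float)
            elif default_diameter is not None:
                pos["diameter"] = float(default_diameter)
            else:
                raise SchemaError(
                    "spots need a diameter_file or default_diameter"
                )
        df = pos.drop(columns=["object_id"])
    elif dialect == "canonical":
        df = pd.read_csv(position_file)
        df.columns = [str(c).strip() for c in df.columns]
        if df.empty:
            raise EmptyInputError(f"{position_file} contains no data rows")
        required = ["id", "frame", "x_um", "y_um"]
        for col in required:
            if col not in df.columns:
                raise SchemaError(col)
        rename = {"x_um": "x", "y_um": "y", "z_um": "z", "diameter_um": "diameter"}
        df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
        if kind == "spots" and "diameter" not in df.columns:
            if default_diameter is None:
                raise SchemaError("diameter_um")
            df["diameter"] = float(default_diameter)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if kind == "tracks":
        df = df.rename(columns={"id": "track_id"})
        keep = [c for c in ("track_id", "frame", "x", "y", "z") if c in df.columns]
        return TrackTable(df[keep], frame_interval=frame_interval)
    df = df.rename(columns={"id": "spot_id"})
    keep = [c for c in ("spot_id", "frame", "x", "y", "z", "diameter") if c in df.columns]
    return SpotTable(df[keep], frame_interval=frame_interval)


def read_tracks(position_file, **kwargs) -> TrackTable:
    """Convenience wrapper: :func:`read_table` with ``kind='tracks'``."""
    return read_table(position_file, kind="tracks", **kwargs)


def read_spots(position_file, **kwargs) -> SpotTable:
    """Convenience wrapper: :func:`read_table` with ``kind='spots'``."""
    return read_table(position_file, kind="spots", **kwargs)


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

# Column contracts of the result CSVs.  Extra columns are preserved.
RESULT_COLUMNS: Mapping[str, list] = {
    "collisions": ["track_id", "spot_id", "frame_start", "frame_end", "min_distance_um"],
    "track_metrics": [
        "track_id",
        "n_points",
        "length_um",
        "displacement_um",
        "straightness",
        "mean_speed_um_s",
        "n_collisions",
        "class",
    ],
    "spot_metrics": ["spot_id", "n_frames", "max_displacement_um", "n_collisions"],
    "cell_summary": [
        "pct_spots_colliding",
        "pct_tracks_colliding",
        "pct_acc",
        "pct_dec",
        "pct_unaffected",
        "pct_acc_str_loss",
    ],
}

# internal episode column -> CSV column
_EPISODE_RENAME = {"min_border_distance": "min_distance_um"}


def write_results(records, path: Union[str, Path], kind: str) -> Path:
    """Write analysis results to CSV under a fixed column contract.

    ``records`` may be a DataFrame, an iterable of mappings, or an iterable
    of dataclasses.  Floats are written with 10 significant digits so that
    values round-trip through :func:`read_results`.
    """
    if kind not in RESULT_COLUMNS:
        raise ValueError(f"unknown result kind {kind!r}")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                from dataclasses import asdict

                rows.append(asdict(rec))
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows)
    df = df.rename(columns=_EPISODE_RENAME)
    required = RESULT_COLUMNS[kind]
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} records missing columns: {missing}")
    ordered = required + [c for c in df.columns if c not in required]
    path = Path(path)
    df[ordered].to_csv(path, index=False, float_format="%.10g")
    return path


def read_results(path: Union[str, Path], kind: str) -> pd.DataFrame:
    """Read a result CSV written by :func:`write_results`.

    Episode tables come back with the internal ``min_border_distance``
    column name so they can feed straight back into the metrics layer.
    """
    if kind not in RESULT_COLUMNS:
        raise ValueError(f"unknown result kind {kind!r}")
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} file missing columns: {missing}")
    inverse = {v: k for k, v in _EPISODE_RENAME.items()}
    return df.rename(columns=inverse)
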