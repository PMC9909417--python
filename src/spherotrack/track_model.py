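"""Calibrated cell-track tables and spot-statistics I/O.

The currency of the whole package is the :class:`TrackTable`: one row per
nucleus per frame, with positions already converted to micrometres and frames
kept as integers.  Time in minutes is always *derived* as
``frame * calibration.frame_interval`` rather than stored, so resampled or
re-calibrated data cannot drift.

Input tables are the "spot statistics" exports of a particle tracker
(TrackMate-style): delimited text with a unique spot ID, a track ID linking
observations of the same nucleus over time, X/Y positions and a frame index.
Two export dialects are handled transparently: the classic single-header
table, and the newer dialect that inserts auxiliary label/unit rows between
the column header and the data (detected as a contiguous block of rows whose
frame field is non-numeric, and skipped).

Spots without a track ID (unlinked detections, routine in tracker exports)
are dropped and counted, never an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParameterError

#: canonical tracker column -> internal name (matched case-insensitively)
SPOT_COLUMNS = {
    "ID": "spot_id",
    "TRACK_ID": "track_id",
    "POSITION_X": "x",
    "POSITION_Y": "y",
    "FRAME": "frame",
}

_INTERNAL_TO_EXPORT = {v: k for k, v in SPOT_COLUMNS.items()}


def normalize_angle_deg(angle):
    """Map angles (deg) into the half-open interval (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = 180.0 - np.mod(180.0 - a, 360.0)
    return float(out) if np.isscalar(angle) or out.ndim == 0 else out


def normalize_axis_deg(axis: float) -> float:
    """Map an axial (mod-180) orientation in degrees into (-90, 90]."""
    return 90.0 - ((90.0 - float(axis)) % 180.0)


@dataclass(frozen=True)
class Calibration:
    """Spatial/temporal calibration and orientation conventions.

    Parameters
    ----------
    pixel_size
        Micrometres per pixel (> 0). Used only when a table is read with
        pixel-unit positions.
    frame_interval
        Minutes per frame (> 0); the acquisition cadence (the assay images
        the nuclear label every 30 min).
    flip_y
        If true, negate y on read: converts the image convention (y grows
        downward) into the mathematical one (y grows upward). All distances
        and speeds are reflection-invariant; only reported angles change.
    fiber_axis_deg
        Orientation of the aligned-fiber axis in degrees, an *axial*
        quantity (defined modulo 180), normalized into (-90, 90]. The
        convention used in the assay puts aligned fibers at +/-90.
    """

    pixel_size: float = 1.0
    frame_interval: float = 30.0
    flip_y: bool = False
    fiber_axis_deg: float = 90.0

    def __post_init__(self):
        if not (self.pixel_size > 0):
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.frame_interval > 0):
            raise ParameterError(f"frame_interval must be > 0, got {self.frame_interval}")
        object.__setattr__(self, "fiber_axis_deg", normalize_axis_deg(self.fiber_axis_deg))


@dataclass
class ReadReport:
    """Bookkeeping from :func:`read_spot_table`."""

    n_spots: int = 0
    n_unlinked_dropped: int = 0
    n_aux_rows_skipped: int = 0


@dataclass
class TrackTable:
    """Calibrated per-nucleus observations.

    ``spots`` holds columns ``spot_id`` (int), ``track_id`` (int), ``x``/``y``
    (float, micrometres) and ``frame`` (int, >= 0), canonically sorted by
    (track_id, frame). One observation per nucleus per frame is enforced.
    """

    spots: pd.DataFrame
    calibration: Calibration = field(default_factory=Calibration)
    source_label: str = ""
    report: ReadReport | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        cols = ["spot_id", "track_id", "x", "y", "frame"]
        if self.spots is None:
            raise ParameterError("spots must not be None")
        missing = [c for c in cols if c not in self.spots.columns]
        if missing:
            raise FormatError(f"spots frame missing columns: {missing}")
        df = self.spots.loc[:, cols].copy()
        if len(df):
            df["spot_id"] = df["spot_id"].astype(np.int64)
            df["track_id"] = df["track_id"].astype(np.int64)
            df["x"] = df["x"].astype(float)
            df["y"] = df["y"].astype(float)
            df["frame"] = df["frame"].astype(np.int64)
            if not np.isfinite(df[["x", "y"]].to_numpy()).all():
                raise IntegrityError("non-finite position encountered")
            if (df["frame"] < 0).any():
                raise IntegrityError("negative frame index encountered")
            dup = df.duplicated(subset=["track_id", "frame"], keep=False)
            if dup.any():
                tid, fr = df.loc[dup, ["track_id", "frame"]].iloc[0]
                raise IntegrityError(
                    f"duplicate observation for (track_id={tid}, frame={fr})"
                )
            df = df.sort_values(["track_id", "frame"], kind="mergesort")
        else:
            df = df.astype(
                {"spot_id": np.int64, "track_id": np.int64, "x": float, "y": float, "frame": np.int64}
            )
        self.spots = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_tracks(self) -> int:
        return int(self.spots["track_id"].nunique())

    @property
    def track_ids(self) -> np.ndarray:
        return self.spots["track_id"].unique()

    @property
    def frames(self) -> np.ndarray:
        """Sorted unique frame indices present in the table."""
        return np.sort(self.spots["frame"].unique())

    def times_min(self) -> pd.Series:
        """Observation times in minutes, derived from frame index."""
        return self.spots["frame"] * self.calibration.frame_interval

    def frame_positions(self, frame: int) -> pd.DataFrame:
        """Rows of one frame (spot_id, track_id, x, y)."""
        return self.spots.loc[self.spots["frame"] == frame].reset_index(drop=True)

    def equals(self, other: "TrackTable") -> bool:
        """Equality of observations (canonical order) and calibration."""
        return (
            self.calibration == other.calibration
            and self.spots.reset_index(drop=True).equals(other.spots.reset_index(drop=True))
        )

    def with_spots(self, spots: pd.DataFrame) -> "TrackTable":
        return replace(self, spots=spots, report=None)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_separator(header_line: str) -> str:
    return "\t" if header_line.count("\t") > header_line.count(",") else ","


def _is_number(s) -> bool:
    if s is None or (isinstance(s, float) and math.isnan(s)):
        return False
    try:
        float(str(s))
        return True
    except ValueError:
        return False


def read_spot_table(
    path,
    calibration: Calibration,
    unit_of_position: str = "um",
    source_label: str | None = None,
) -> TrackTable:
    """Read a tracker spot-statistics export into a :class:`TrackTable`.

    Parameters
    ----------
    path
        Delimited text file (comma- or tab-separated, sniffed from the
        header) with columns matched case-insensitively to
        ``ID, TRACK_ID, POSITION_X, POSITION_Y, FRAME``; extra columns are
        ignored.
    calibration
        Supplies ``pixel_size`` (applied when ``unit_of_position="pixel"``)
        and the ``flip_y`` orientation convention.
    unit_of_position
        ``"um"`` (positions already micrometres) or ``"pixel"``.

    Returns
    -------
    TrackTable
        With a :class:`ReadReport` attached as ``.report`` counting dropped
        unlinked spots and skipped auxiliary header rows.
    """
    if unit_of_position not in ("um", "pixel"):
        raise ParameterError(f"unit_of_position must be 'um' or 'pixel', got {unit_of_position!r}")
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"empty file: {path}")
    sep = _sniff_separator(lines[0])
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc

    upper = {str(c).strip().upper(): c for c in raw.columns}
    colmap = {}
    for canonical, internal in SPOT_COLUMNS.items():
        if canonical not in upper:
            raise FormatError(f"missing required column {canonical!r} in {path}")
        colmap[internal] = upper[canonical]
    df = raw.loc[:, [colmap[k] for k in ("spot_id", "track_id", "x", "y", "frame")]].copy()
    df.columns = ["spot_id", "track_id", "x", "y", "frame"]

    # auxiliary metadata rows of the multi-header export dialect: a contiguous
    # block right below the header whose frame field is non-numeric
    n_aux = 0
    while n_aux < len(df) and not _is_number(df["frame"].iloc[n_aux]):
        n_aux += 1
    df = df.iloc[n_aux:]

    # unlinked spots: missing / non-numeric track ID
    linked = df["track_id"].map(_is_number)
    n_unlinked = int((~linked).sum())
    df = df.loc[linked]

    out = pd.DataFrame(index=df.index)
    for col, kind in (("spot_id", int), ("x", float), ("y", float), ("frame", int)):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df[col][vals.isna()].iloc[0]
            raise FormatError(
                f"non-numeric value {bad!r} in column {_INTERNAL_TO_EXPORT[col]} of {path}"
            )
        out[col] = vals.astype(float) if kind is float else vals.astype(float).round().astype(np.int64)
    out["track_id"] = pd.to_numeric(df["track_id"]).astype(float).round().astype(np.int64)

    if unit_of_position == "pixel":
        out["x"] *= calibration.pixel_size
        out["y"] *= calibration.pixel_size
    if calibration.flip_y:
        out["y"] = -out["y"]

    table = TrackTable(
        spots=out[["spot_id", "track_id", "x", "y", "frame"]],
        calibration=calibration,
        source_label=source_label if source_label is not None else path.stem,
    )
    table.report = ReadReport(
        n_spots=len(out), n_unlinked_dropped=n_unlinked, n_aux_rows_skipped=n_aux
    )
    return table


@dataclass
class FilterReport:
    """Which tracks :func:`filter_tracks` removed and why."""

    removed: list = field(default_factory=list)  # (track_id, reason)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["track_id", "reason"])


def filter_tracks(
    table: TrackTable, min_points: int = 2, min_accumulated_um: float = 0.0
) -> tuple[TrackTable, FilterReport]:
    """Drop short or immobile tracks (programmatic dead-cell cleanup).

    A track is removed when it has fewer than ``min_points`` observations, or
    when its accumulated path length is strictly below ``min_accumulated_um``.
    The defaults (2 points, 0 um) remove only single-observation tracks,
    which carry no displacement information.
    """
    if min_points < 1:
        raise ParameterError(f"min_points must be >= 1, got {min_points}")
    if min_accumulated_um < 0:
        raise ParameterError(f"min_accumulated_um must be >= 0, got {min_accumulated_um}")
    df = table.spots
    removed = []
    keep_ids = []
    for tid, grp in df.groupby("track_id", sort=True):
        if len(grp) < min_points:
            removed.append((int(tid), "too_few_points"))
            continue
        acc = float(np.hypot(np.diff(grp["x"].to_numpy()), np.diff(grp["y"].to_numpy())).sum())
        if acc < min_accumulated_um:
            removed.append((int(tid), "below_min_accumulated"))
            continue
        keep_ids.append(tid)
    kept = df[df["track_id"].isin(keep_ids)].reset_index(drop=True)
    return table.with_spots(kept), FilterReport(removed=removed)


def write_table(records, path) -> None:
    """Write any tabular result as comma-separated text with one header row.

    Accepts a :class:`TrackTable` (written with the tracker's canonical
    column names so it round-trips through :func:`read_spot_table`), a
    pandas DataFrame, or any object exposing ``to_frame()``. Floats keep
    10 significant digits; missing values are rendered ``NaN``.
    """
    if records is None:
        raise ParameterError("records must not be None")
    if isinstance(records, TrackTable):
        df = records.spots.rename(columns=_INTERNAL_TO_EXPORT)
    elif isinstance(records, pd.DataFrame):
        df = records
    elif hasattr(records, "to_frame"):
        df = records.to_frame()
    else:
        raise ParameterError(f"cannot serialize object of type {type(records).__name__}")
    df.to_csv(path, index=False, float_format="%.10g", na_rep="NaN")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (``NaN`` aware)."""
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty file: {path}") from exc
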