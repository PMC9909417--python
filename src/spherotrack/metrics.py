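"""Per-cell and population migration metrics.

Everything here is built from *steps*: the displacement between two
consecutive observations of the same track.  Steps are gap-aware — when the
upstream linker closed a detection gap, ``dt`` spans the actual frame
difference, so speeds stay honest.

Directionality is deliberately split into three named quantities that the
field often lumps under one word:

* ``angle_deg`` — the instantaneous direction of a single step,
* ``net_direction_deg`` — the direction of a track's start-to-end displacement,
* ``directionality_ratio`` — Euclidean / accumulated distance in [0, 1]
  (1 for perfectly straight motion).

Angles live in degrees in (-180, 180], measured counter-clockwise from +x.
A zero-length step has no direction; its angle is NaN and it is excluded
from every angular statistic (it still contributes speed 0 to speed
statistics).  Contact guidance on aligned fibers is summarized by the
nematic alignment order parameter S = <cos 2(theta - phi)> with phi the
fiber axis: +1 parallel, 0 isotropic, -1 perpendicular; directions are
treated as axial (theta and theta+180 equivalent), which the doubled angle
does automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .track_model import TrackTable, normalize_angle_deg

STEP_COLUMNS = [
    "track_id", "frame_from", "frame_to", "spot_id_from", "spot_id_to",
    "dt", "dx", "dy", "step_length", "speed", "angle_deg",
]

TRACK_METRIC_COLUMNS = [
    "track_id", "n_points", "total_time", "accumulated_distance",
    "euclidean_distance", "mean_speed", "median_speed",
    "directionality_ratio", "net_direction_deg",
]


def _empty_steps() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in STEP_COLUMNS}).astype(
        {"track_id": np.int64, "frame_from": np.int64, "frame_to": np.int64,
         "spot_id_from": np.int64, "spot_id_to": np.int64}, errors="ignore"
    )


def compute_steps(table: TrackTable) -> pd.DataFrame:
    """One row per consecutive pair of observations within each track.

    Columns: track_id, frame_from, frame_to, spot_id_from, spot_id_to,
    dt (min), dx, dy, step_length (um), speed (um/min), angle_deg
    (NaN for zero-length steps). Single-observation tracks yield no rows.
    """
    df = table.spots  # canonically sorted by (track_id, frame)
    if len(df) < 2:
        return _empty_steps()
    tid = df["track_id"].to_numpy()
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    fr = df["frame"].to_numpy()
    sid = df["spot_id"].to_numpy()
    same = tid[1:] == tid[:-1]
    if not same.any():
        return _empty_steps()
    dx = (x[1:] - x[:-1])[same]
    dy = (y[1:] - y[:-1])[same]
    dframe = (fr[1:] - fr[:-1])[same]
    dt = dframe * table.calibration.frame_interval
    length = np.hypot(dx, dy)
    with np.errstate(invalid="ignore"):
        angle = normalize_angle_deg(np.degrees(np.arctan2(dy, dx)))
    angle = np.where(length > 0, angle, np.nan)
    return pd.DataFrame({
        "track_id": tid[1:][same],
        "frame_from": fr[:-1][same],
        "frame_to": fr[1:][same],
        "spot_id_from": sid[:-1][same],
        "spot_id_to": sid[1:][same],
        "dt": dt,
        "dx": dx,
        "dy": dy,
        "step_length": length,
        "speed": length / dt,
        "angle_deg": angle,
    })


def track_metrics(table: TrackTable, steps: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-track summary metrics.

    * accumulated_distance — total path length (sum of step lengths, um)
    * euclidean_distance — |last position - first position| (um)
    * mean_speed — accumulated distance / elapsed time (um/min); elapsed
      time is (last frame - first frame) x frame_interval, so the measure is
      robust to gap-closed tracks with unequal step durations
    * median_speed — median of per-step speeds
    * directionality_ratio — euclidean / accumulated, NaN when the track
      never moved (0/0)
    * net_direction_deg — angle of the start-to-end displacement, NaN when
      euclidean distance is 0

    Single-observation tracks get zero distances and NaN speeds/ratios.
    """
    df = table.spots
    if df.empty:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in TRACK_METRIC_COLUMNS})
    if steps is None:
        steps = compute_steps(table)
    interval = table.calibration.frame_interval

    g = df.groupby("track_id", sort=True)
    first = g.first()
    last = g.last()
    out = pd.DataFrame(index=first.index)
    out["n_points"] = g.size()
    out["total_time"] = (last["frame"] - first["frame"]) * interval
    if len(steps):
        acc = steps.groupby("track_id")["step_length"].sum()
        med = steps.groupby("track_id")["speed"].median()
    else:
        acc = pd.Series(dtype=float)
        med = pd.Series(dtype=float)
    out["accumulated_distance"] = acc.reindex(out.index).fillna(0.0)
    ex = last["x"] - first["x"]
    ey = last["y"] - first["y"]
    out["euclidean_distance"] = np.hypot(ex, ey)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["mean_speed"] = np.where(
            out["total_time"] > 0, out["accumulated_distance"] / out["total_time"], np.nan
        )
        out["directionality_ratio"] = np.where(
            out["accumulated_distance"] > 0,
            out["euclidean_distance"] / out["accumulated_distance"],
            np.nan,
        )
    out["median_speed"] = med.reindex(out.index)
    net = normalize_angle_deg(np.degrees(np.arctan2(ey.to_numpy(), ex.to_numpy())))
    out["net_direction_deg"] = np.where(out["euclidean_distance"] > 0, net, np.nan)
    return out.reset_index()[TRACK_METRIC_COLUMNS]


def instantaneous_series(table: TrackTable, steps: pd.DataFrame | None = None) -> pd.DataFrame:
    """Population time series of instantaneous speed and alignment.

    For each frame ``f`` with at least one step ending there: the number of
    contributing tracks, mean and SEM (n-1 variance, NaN below 2 cells) of
    step speed, and the mean alignment order of the defined step angles
    relative to the calibrated fiber axis. Frames with no steps are omitted.
    """
    if steps is None:
        steps = compute_steps(table)
    if steps.empty:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in
                             ["frame", "n_cells", "mean_speed", "sem_speed", "mean_alignment"]})
    axis = table.calibration.fiber_axis_deg
    rows = []
    for f, grp in steps.groupby("frame_to", sort=True):
        sp = grp["speed"].to_numpy()
        n = len(sp)
        sem = float(np.std(sp, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        ang = grp["angle_deg"].to_numpy()
        ang = ang[np.isfinite(ang)]
        align = alignment_order(ang, axis) if ang.size else np.nan
        rows.append((int(f), n, float(np.mean(sp)), sem, align))
    return pd.DataFrame(rows, columns=["frame", "n_cells", "mean_speed", "sem_speed", "mean_alignment"])


@dataclass(frozen=True)
class PolarHistogram:
    """Probability distribution of motion direction over (-180, 180]."""

    bin_edges_deg: np.ndarray
    probabilities: np.ndarray
    n_angles: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_deg": self.bin_edges_deg[:-1],
            "bin_hi_deg": self.bin_edges_deg[1:],
            "probability": self.probabilities,
        })


def polar_distribution(angles, n_bins: int = 24) -> PolarHistogram:
    """Histogram of direction angles as per-bin probabilities.

    Equal-width half-open bins ``[lo, hi)`` covering (-180, 180], with the
    final bin closed at 180; angles are normalized into (-180, 180] first.
    Probabilities are counts / n_angles and sum to 1 for non-empty input;
    non-finite (undefined-direction) entries are ignored.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    a = np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles, dtype=float).ravel()
    a = a[np.isfinite(a)]
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    if a.size == 0:
        return PolarHistogram(edges, np.zeros(n_bins), 0)
    a = normalize_angle_deg(a)
    counts, _ = np.histogram(a, bins=edges)
    return PolarHistogram(edges, counts / a.size, int(a.size))


def alignment_order(angles, fiber_axis_deg: float) -> float:
    """Nematic alignment order parameter S = <cos 2(theta - phi)> in [-1, 1].

    Directions are axial: adding 180 deg to any angle leaves S unchanged.
    S = 1 when all motion is parallel to the fiber axis ``phi``, ~0 for
    isotropic motion, -1 when all motion is perpendicular. NaN for empty
    input (undefined).
    """
    a = np.asarray(list(angles) if not isinstance(angles, np.ndarray) else angles, dtype=float).ravel()
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    return float(np.mean(np.cos(2.0 * np.radians(a - fiber_axis_deg))))


@dataclass(frozen=True)
class SpeedBinnedDirectionality:
    """Polar direction distributions of tracks partitioned by mean speed.

    ``per_bin[i]`` is ``(track_ids, PolarHistogram)`` for the i-th speed bin;
    the bins partition the table's tracks.
    """

    bin_edges_speed: np.ndarray
    per_bin: list  # of (frozenset of track_id, PolarHistogram)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (tids, hist) in enumerate(self.per_bin):
            for lo, hi, p in zip(hist.bin_edges_deg[:-1], hist.bin_edges_deg[1:], hist.probabilities):
                rows.append((i, self.bin_edges_speed[i], self.bin_edges_speed[i + 1],
                             len(tids), hist.n_angles, lo, hi, p))
        return pd.DataFrame(rows, columns=[
            "speed_bin", "speed_lo", "speed_hi", "n_tracks", "n_angles",
            "angle_lo_deg", "angle_hi_deg", "probability"])


def bin_by_speed(
    table: TrackTable,
    n_bins: int = 4,
    edges=None,
    polar_bins: int = 24,
    steps: pd.DataFrame | None = None,
) -> SpeedBinnedDirectionality:
    """Partition tracks into speed bins and pool their step angles.

    When ``edges`` is not given, bins are the quartile-style quantiles of
    per-track mean speed (``n_bins + 1`` edges). Bins are half-open
    ``[lo, hi)`` with the last bin closed, so ties at an edge go upward;
    every track lands in exactly one bin. Each bin carries the polar
    distribution of all step angles of its member tracks.
    """
    if steps is None:
        steps = compute_steps(table)
    tm = track_metrics(table, steps=steps)
    speeds = tm["mean_speed"].to_numpy()
    if np.isnan(speeds).any():
        bad = tm.loc[np.isnan(speeds), "track_id"].tolist()
        raise ParameterError(f"tracks without a defined mean speed: {bad}")
    if edges is None:
        if n_bins < 1:
            raise ParameterError(f"n_bins must be >= 1, got {n_bins}")
        edges = np.quantile(speeds, np.linspace(0.0, 1.0, n_bins + 1)) if speeds.size else np.zeros(n_bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) < 0):
            raise ParameterError("explicit speed bin edges must be a monotone 1-d sequence")
        n_bins = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, speeds, side="right") - 1, 0, n_bins - 1)
    per_bin = []
    for b in range(n_bins):
        tids = frozenset(int(t) for t in tm.loc[idx == b, "track_id"])
        ang = steps.loc[steps["track_id"].isin(tids), "angle_deg"].to_numpy() if tids else np.array([])
        per_bin.append((tids, polar_distribution(ang, polar_bins)))
    return SpeedBinnedDirectionality(np.asarray(edges, dtype=float), per_bin)
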