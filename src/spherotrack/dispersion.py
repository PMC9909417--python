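"""Single-cell dispersion: per-frame nearest-neighbor classification.

A nucleus is "single" (detached from the collectively migrating sheet) in a
given frame when its Euclidean distance to the nearest other nucleus in that
frame is *strictly greater* than a user-set threshold (default 40 um; the
value is cell-line-specific and should be checked against phase-contrast
video).  A lone nucleus in a frame is single by definition.  Classification
is per-frame and memoryless — a cell may be single at one time point and
group later.

Strictness at the boundary (distance == threshold counts as group) is part
of the contract so results are reproducible bit-for-bit.  The spatial index
(cKDTree) is an implementation detail; its labels match the all-pairs
definition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import IntegrityError, ParameterError
from .metrics import compute_steps
from .track_model import TrackTable

SINGLE = "single"
GROUP = "group"


@dataclass
class FrameClassification:
    """Labels and nearest-neighbor distances for the nuclei of one frame."""

    frame: int
    spot_ids: np.ndarray
    is_single: np.ndarray        # bool, aligned with spot_ids
    nn_distance: np.ndarray      # um; NaN when the frame has a single nucleus
    threshold: float

    @property
    def labels(self) -> dict:
        """spot_id -> "single" | "group"."""
        return {int(s): (SINGLE if b else GROUP)
                for s, b in zip(self.spot_ids, self.is_single)}

    @property
    def nn_distances(self) -> dict:
        return {int(s): float(d) for s, d in zip(self.spot_ids, self.nn_distance)}

    @property
    def n_total(self) -> int:
        return len(self.spot_ids)

    @property
    def n_single(self) -> int:
        return int(self.is_single.sum())

    @property
    def single_ids(self) -> frozenset:
        return frozenset(int(s) for s in self.spot_ids[self.is_single])


def nearest_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest *other* point (NaN if alone)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([np.nan])
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


def classify_frame(
    points: np.ndarray,
    threshold: float,
    spot_ids=None,
    frame: int = 0,
) -> FrameClassification:
    """Label every nucleus of one frame single/group by nearest-neighbor distance.

    ``points`` is an (n, 2) array of positions in micrometres. A nucleus is
    single iff its nearest-neighbor distance exceeds ``threshold`` strictly,
    or it is alone in the frame.
    """
    if not (threshold > 0):
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if spot_ids is None:
        spot_ids = np.arange(n)
    spot_ids = np.asarray(spot_ids)
    if len(spot_ids) != n:
        raise ParameterError("spot_ids length must match number of points")
    nn = nearest_neighbor_distances(pts)
    if n == 1:
        is_single = np.array([True])
    else:
        is_single = nn > threshold
    return FrameClassification(int(frame), spot_ids, is_single, nn, float(threshold))


@dataclass
class DispersionResult:
    """Per-frame single/group census for one threshold."""

    threshold: float
    classifications: dict = field(default_factory=dict)  # frame -> FrameClassification

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in sorted(self.classifications):
            c = self.classifications[f]
            ratio = c.n_single / c.n_total if c.n_total else np.nan
            ids = ";".join(str(s) for s in sorted(c.single_ids))
            rows.append((self.threshold, f, c.n_total, c.n_single, ratio, ids))
        return pd.DataFrame(rows, columns=[
            "threshold", "frame", "n_total", "n_single", "ratio", "single_ids"])


def dispersion_timeseries(table: TrackTable, threshold: float) -> DispersionResult:
    """Classify every frame of the table; census in frame order."""
    if not (threshold > 0):
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    result = DispersionResult(threshold=float(threshold))
    for f in table.frames:
        rows = table.frame_positions(int(f))
        result.classifications[int(f)] = classify_frame(
            rows[["x", "y"]].to_numpy(), threshold,
            spot_ids=rows["spot_id"].to_numpy(), frame=int(f))
    return result


def threshold_sweep(table: TrackTable, thresholds) -> dict:
    """Dispersion time series for each threshold; keyed by threshold."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ParameterError("thresholds must be non-empty")
    for t in thresholds:
        if not (t > 0):
            raise ParameterError(f"thresholds must be positive, got {t}")
    return {float(t): dispersion_timeseries(table, float(t)) for t in thresholds}


def sweep_table(sweep: dict) -> pd.DataFrame:
    """Long-format table of a threshold sweep, keyed by (threshold, frame)."""
    frames = [sweep[t].to_frame() for t in sorted(sweep)]
    if not frames:
        return pd.DataFrame(columns=["threshold", "frame", "n_total", "n_single", "ratio", "single_ids"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class ClassSplitResult:
    """Migration statistics split by single/group class.

    ``series``: per (frame, class) mean +/- SEM step speed and cell count.
    ``angles``: long-format per-step angles (frame, track_id, class,
    angle_deg), the per-dot structure of instantaneous single-cell
    directionality plots; feed a class's angles to ``polar_distribution``
    or ``alignment_order``.
    """

    series: pd.DataFrame
    angles: pd.DataFrame


def split_metrics_by_class(table: TrackTable, classifications: dict) -> ClassSplitResult:
    """Assign each step the class of its nucleus at the step's end frame.

    ``classifications`` maps frame -> :class:`FrameClassification` and must
    cover every frame at which a step of the table ends.
    """
    steps = compute_steps(table)
    label_of = {}
    for f, c in classifications.items():
        for s, b in zip(c.spot_ids, c.is_single):
            label_of[(int(f), int(s))] = SINGLE if b else GROUP

    cls = []
    for f, s in zip(steps["frame_to"].to_numpy(), steps["spot_id_to"].to_numpy()):
        key = (int(f), int(s))
        if key not in label_of:
            raise IntegrityError(f"no classification for spot {s} at frame {f}")
        cls.append(label_of[key])
    steps = steps.assign(cell_class=cls) if len(steps) else steps.assign(cell_class=pd.Series(dtype=object))

    rows = []
    for (f, c), grp in steps.groupby(["frame_to", "cell_class"], sort=True):
        sp = grp["speed"].to_numpy()
        n = len(sp)
        sem = float(np.std(sp, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append((int(f), c, n, float(np.mean(sp)), sem))
    series = pd.DataFrame(rows, columns=["frame", "cell_class", "n_cells", "mean_speed", "sem_speed"])

    ang = steps.loc[np.isfinite(steps["angle_deg"].to_numpy())] if len(steps) else steps
    angles = ang[["frame_to", "track_id", "cell_class", "angle_deg"]].rename(
        columns={"frame_to": "frame"}).reset_index(drop=True)
    return ClassSplitResult(series=series, angles=angles)


# ---------------------------------------------------------------------------
# overlay rendering
# ---------------------------------------------------------------------------

_GREY = (150, 150, 150)
_SINGLE_COLOR = (214, 39, 40)
_BG = (255, 255, 255)
_STAMP = (0, 0, 0)


def render_overlay(
    table: TrackTable,
    classifications: dict,
    out_dir,
    fmt: str = "png-sequence",
    dot_radius_px: int = 4,
    target_px: int = 600,
) -> list:
    """Render one raster frame per time point with class-colored nuclei.

    Group nuclei are grey, single nuclei red; the world-to-pixel mapping is
    fixed across frames (global bounding box plus margin) so motion is
    visually comparable, and the frame index and threshold are stamped in
    the top-left corner. ``fmt`` is ``"png-sequence"`` (lossless, the
    contract) or ``"animated-gif"``. Rendering is deterministic: the same
    table renders to byte-identical files.
    """
    from PIL import Image, ImageDraw

    if fmt not in ("png-sequence", "animated-gif"):
        raise ParameterError(f"unknown overlay format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    df = table.spots
    if len(df):
        xmin, xmax = float(df["x"].min()), float(df["x"].max())
        ymin, ymax = float(df["y"].min()), float(df["y"].max())
    else:
        xmin = ymin = 0.0
        xmax = ymax = 1.0
    span = max(xmax - xmin, ymax - ymin, 1e-9)
    margin = 0.05 * span
    xmin -= margin; xmax += margin; ymin -= margin; ymax += margin
    scale = target_px / max(xmax - xmin, ymax - ymin)
    W = max(int(np.ceil((xmax - xmin) * scale)), 64)
    H = max(int(np.ceil((ymax - ymin) * scale)), 64)

    def to_px(x, y):
        # y inverted for display: larger y plots higher in the image
        return ((x - xmin) * scale, H - (y - ymin) * scale)

    frames_sorted = sorted(classifications)
    threshold = classifications[frames_sorted[0]].threshold if frames_sorted else None
    images = []
    paths = []
    for f in frames_sorted:
        c = classifications[f]
        img = Image.new("RGB", (W, H), _BG)
        draw = ImageDraw.Draw(img)
        rows = table.frame_positions(int(f)).set_index("spot_id")
        order = np.argsort(c.spot_ids, kind="stable")
        for i in order:
            sid = int(c.spot_ids[i])
            px, py = to_px(float(rows.at[sid, "x"]), float(rows.at[sid, "y"]))
            color = _SINGLE_COLOR if c.is_single[i] else _GREY
            r = dot_radius_px
            draw.ellipse([px - r, py - r, px + r, py + r], fill=color)
        stamp = f"frame {f}"
        if threshold is not None:
            stamp += f"  threshold {threshold:g} um"
        draw.text((5, 5), stamp, fill=_STAMP)
        images.append(img)
        if fmt == "png-sequence":
            p = out_dir / f"frame_{f:04d}.png"
            img.save(p, format="PNG")
            paths.append(p)
    if fmt == "animated-gif":
        p = out_dir / "overlay.gif"
        if images:
            images[0].save(p, format="GIF", save_all=True,
                           append_images=images[1:], duration=100, loop=0)
            paths.append(p)
    return paths
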