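"""End-to-end analysis: read -> filter -> metrics -> dispersion -> overlay.

One spheroid's tracking export in, a directory of plain comma-separated
result tables plus a JSON run manifest out.  The manifest records the
configuration snapshot, software version, input checksum and per-stage row
counts, and asserts the structural identity ``n_steps = n_spots - n_tracks``
(every track contributes one fewer step than observations).  Nothing
time-stamped goes into the outputs, so a re-run on identical input is
byte-identical.

Aggregation across spheroids (the assay analyzes each spheroid
independently, then pools per condition) is a separate concatenation step
that adds a condition column.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .dispersion import (dispersion_timeseries, render_overlay, split_metrics_by_class,
                         sweep_table, threshold_sweep)
from .errors import PipelineError, SpherotrackError
from .metrics import (bin_by_speed, compute_steps, instantaneous_series,
                      polar_distribution, track_metrics)
from .track_model import filter_tracks, read_spot_table, read_table, write_table

log = logging.getLogger("spherotrack")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_full_analysis(tracks_path, config: RunConfig) -> dict:
    """Run the whole measurement workflow on one spot-statistics export.

    Writes, under ``config.output_dir``: the filtered track table, per-track
    metrics, steps, the instantaneous series, the pooled polar histogram,
    speed-binned directionality, the dispersion census (plus a threshold
    sweep when requested), class-split statistics, the single-cell angle
    table, overlay frames, and ``manifest.json``. Returns the manifest.
    Any stage failure aborts with a stage-named error and a manifest marked
    incomplete.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "spherotrack",
        "version": __version__,
        "input": str(tracks_path),
        "input_sha256": _sha256(tracks_path),
        "config": config.to_dict(),
        "row_counts": {},
        "artifacts": [],
        "status": "incomplete",
    }
    counts = manifest["row_counts"]
    artifacts = manifest["artifacts"]

    def save(obj, name):
        path = out_dir / name
        write_table(obj, path)
        artifacts.append(name)
        return path

    stage = "read"
    try:
        t0 = time.perf_counter()
        table = read_spot_table(tracks_path, config.calibration,
                                unit_of_position=config.unit_of_position)
        counts["spots_raw"] = table.n_spots
        counts["unlinked_dropped"] = table.report.n_unlinked_dropped
        log.info("read: %d spots, %d tracks (%.2fs)", table.n_spots, table.n_tracks,
                 time.perf_counter() - t0)

        stage = "filter"
        table, filt_report = filter_tracks(table, config.min_points, config.min_accumulated_um)
        counts["spots_filtered"] = table.n_spots
        counts["n_tracks"] = table.n_tracks
        counts["tracks_removed"] = filt_report.n_removed
        save(table, "tracks_filtered.csv")
        if table.n_spots == 0:
            log.warning("filter: no tracks survive filtering; downstream tables will be empty")

        stage = "steps"
        steps = compute_steps(table)
        counts["steps"] = len(steps)
        assert len(steps) == table.n_spots - table.n_tracks, "step/spot count identity violated"
        save(steps, "steps.csv")

        stage = "track_metrics"
        tm = track_metrics(table, steps=steps)
        save(tm, "track_metrics.csv")

        stage = "instantaneous_series"
        series = instantaneous_series(table, steps=steps)
        counts["series_frames"] = len(series)
        save(series, "instantaneous_series.csv")

        stage = "polar"
        angles = steps["angle_deg"].to_numpy() if len(steps) else np.array([])
        hist = polar_distribution(angles, config.polar_bins)
        save(hist, "polar.csv")

        stage = "speed_binned_directionality"
        if len(tm) and not tm["mean_speed"].isna().any():
            sbd = bin_by_speed(table, n_bins=config.speed_bins,
                               polar_bins=config.polar_bins, steps=steps)
            save(sbd, "speed_binned_polar.csv")
        else:
            if len(tm):
                log.warning("speed binning skipped: some tracks have undefined mean speed")
            save(pd.DataFrame(columns=["speed_bin", "speed_lo", "speed_hi", "n_tracks",
                                       "n_angles", "angle_lo_deg", "angle_hi_deg",
                                       "probability"]), "speed_binned_polar.csv")

        stage = "dispersion"
        if table.n_spots:
            main = dispersion_timeseries(table, config.dispersion_threshold)
            disp_tables = {config.dispersion_threshold: main}
            if config.sweep_thresholds:
                disp_tables.update(threshold_sweep(table, config.sweep_thresholds))
            save(sweep_table(disp_tables), "dispersion.csv")
            counts["dispersion_frames"] = len(main.classifications)
        else:
            main = None
            save(pd.DataFrame(columns=["threshold", "frame", "n_total", "n_single",
                                       "ratio", "single_ids"]), "dispersion.csv")
            counts["dispersion_frames"] = 0

        stage = "class_split"
        if main is not None:
            split = split_metrics_by_class(table, main.classifications)
            save(split.series, "class_split.csv")
            save(split.angles.loc[split.angles["cell_class"] == "single"]
                 .drop(columns=["cell_class"]), "single_angles.csv")
        else:
            save(pd.DataFrame(columns=["frame", "cell_class", "n_cells", "mean_speed",
                                       "sem_speed"]), "class_split.csv")
            save(pd.DataFrame(columns=["frame", "track_id", "angle_deg"]), "single_angles.csv")

        stage = "overlay"
        if config.overlay_format and main is not None:
            paths = render_overlay(table, main.classifications,
                                   out_dir / "overlay", fmt=config.overlay_format)
            counts["overlay_frames"] = len(paths)
            artifacts.append("overlay/")
    except SpherotrackError as exc:
        manifest["status"] = f"failed at stage '{stage}': {exc}"
        _write_manifest(manifest, out_dir)
        raise PipelineError(f"stage '{stage}': {exc}") from exc

    manifest["status"] = "complete"
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path):
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def aggregate_track_metrics(inputs: dict, out_path) -> pd.DataFrame:
    """Concatenate per-spheroid ``track_metrics.csv`` files across conditions.

    ``inputs`` maps a condition label (e.g. "glass", "aligned") to one or
    more table paths; the result gains ``condition`` and ``source`` columns
    and is written to ``out_path``.
    """
    frames = []
    for condition, paths in inputs.items():
        if isinstance(paths, (str, Path)):
            paths = [paths]
        for p in paths:
            df = read_table(p)
            df.insert(0, "condition", condition)
            df.insert(1, "source", str(p))
            frames.append(df)
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    write_table(combined, out_path)
    return combined
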