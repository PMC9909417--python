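"""Run configuration: defaults, YAML config files, CLI overrides.

Every field has a valid default so the pipeline runs with no config file at
all; a YAML file can override any field, and explicit CLI flags win over
the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import yaml

from .errors import FormatError, ParameterError
from .track_model import Calibration


@dataclass(frozen=True)
class RunConfig:
    """User-set constants of a full analysis run."""

    calibration: Calibration = field(default_factory=Calibration)
    min_points: int = 2
    min_accumulated_um: float = 0.0
    dispersion_threshold: float = 40.0       # um; cell-line specific, user-set
    sweep_thresholds: tuple = ()             # e.g. (30, 50, 100)
    polar_bins: int = 24
    speed_bins: int = 4
    unit_of_position: str = "um"
    overlay_format: str = "png-sequence"     # or "animated-gif" or "" to skip
    output_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.dispersion_threshold <= 0:
            raise ParameterError("dispersion_threshold must be > 0")
        if self.polar_bins < 2 or self.speed_bins < 1:
            raise ParameterError("polar_bins must be >= 2 and speed_bins >= 1")
        object.__setattr__(self, "sweep_thresholds", tuple(float(t) for t in self.sweep_thresholds))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweep_thresholds"] = list(self.sweep_thresholds)
        return d


_CALIBRATION_KEYS = {"pixel_size", "frame_interval", "flip_y", "fiber_axis_deg"}
_FILTER_KEYS = {"min_points", "min_accumulated_um"}


def load_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    The file may contain ``calibration:`` and ``filtering:`` sections plus
    top-level keys (``dispersion_threshold``, ``sweep_thresholds``,
    ``polar_bins``, ...). Keyword ``overrides`` (typically CLI flags) win
    over the file; ``None`` overrides are ignored. Calibration fields may
    be overridden with their own names (e.g. ``pixel_size=...``).
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must be a mapping")
        data = dict(raw)

    cal_kwargs = dict(data.pop("calibration", {}) or {})
    filt = dict(data.pop("filtering", {}) or {})
    data.update(filt)

    for k, v in overrides.items():
        if v is None:
            continue
        if k in _CALIBRATION_KEYS:
            cal_kwargs[k] = v
        else:
            data[k] = v

    unknown_cal = set(cal_kwargs) - _CALIBRATION_KEYS
    if unknown_cal:
        raise FormatError(f"unknown calibration keys: {sorted(unknown_cal)}")
    known = {f for f in RunConfig.__dataclass_fields__} - {"calibration"}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")

    return RunConfig(calibration=Calibration(**cal_kwargs), **data)
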