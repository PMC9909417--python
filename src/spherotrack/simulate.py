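"""Agent-based synthetic spheroid-outgrowth tracks.

The generator emulates the statistical structure of a spheroid-outgrowth
assay as a particle tracker sees it: cells leave the rim of a spheroid and
migrate outward as a biased persistent random walk, with per-cell speed
heterogeneity, substrate-dependent directional (contact-guidance) bias,
loose cohesion of the collectively migrating group, and stochastic
detachment of single cells.  It emits an already-linked :class:`TrackTable`
plus per-observation ground truth, so every downstream stage — metrics,
speed binning, KNN dispersion classification — can be tested against known
generating parameters without any microscopy data.

Model per frame, for each cell:

1. new cells are released on the spheroid rim at ``release_rate`` per frame
   (fractional rates are carried over between frames);
2. each group cell detaches with probability ``p_detach``; detachment is
   absorbing (singles never rejoin), scales the cell speed by
   ``detach_speed_factor`` and re-aims the heading away from the nearest
   group neighbor, so a detaching cell breaks away from the sheet within
   its detachment frame;
3. a new heading is drawn by combining a persistence kernel (von Mises
   around the previous heading, concentration ``persistence_kappa``) with an
   axial contact-guidance kernel toward ``fiber_axis_deg`` (axial von Mises,
   concentration ``fiber_bias_kappa``); the two circular densities multiply,
   sampled exactly by rejection with the persistence kernel as proposal;
4. the cell advances by its speed x frame interval; a group cell that ends
   farther than ``cohesion_radius`` from its nearest group neighbor is
   pulled back along that line to the cohesion radius;
5. positions are emitted with isotropic Gaussian localization noise of
   ``position_noise_sd`` (observation noise only — the dynamics use the
   true positions).

Each cell owns an independent random stream spawned from (seed, track_id),
so adding or removing cells never perturbs the draws of other cells, and an
identical configuration reproduces bit-identical output.

The spheroid body itself is not emitted — like the real assay, where the
opaque core cannot be tracked, only outgrowing cells produce spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError
from .track_model import Calibration, TrackTable, normalize_angle_deg, normalize_axis_deg


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic spheroid-outgrowth model.

    Defaults emulate a 24-h acquisition at 30-min cadence (48 frames) of a
    moderately motile epithelial-like outgrowth: mean cell speed 0.5 um/min
    with 40% between-cell variation (lognormal), persistent but isotropic
    walks (glass-like substrate, ``fiber_bias_kappa = 0``), loose cohesion
    at 25 um, and a 1%-per-frame detachment hazard with detached cells
    moving 1.5x faster.
    """

    n_cells_initial: int = 60
    release_rate: float = 3.0        # cells released from the rim per frame
    spheroid_radius: float = 150.0   # um
    n_frames: int = 48
    frame_interval: float = 30.0     # min
    speed_mean: float = 0.5          # um/min, mean of per-cell lognormal
    speed_cv: float = 0.4            # coefficient of variation of cell speeds
    persistence_kappa: float = 2.0   # heading persistence (0 = pure random walk)
    fiber_bias_kappa: float = 0.0    # axial contact-guidance strength (0 = isotropic)
    fiber_axis_deg: float = 90.0
    p_detach: float = 0.01           # per-cell per-frame detachment probability
    detach_speed_factor: float = 1.5
    cohesion_radius: float = 25.0    # um, max distance from nearest group neighbor
    position_noise_sd: float = 1.0   # um localization jitter (observation only)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells_initial < 0 or self.n_frames < 1:
            raise ParameterError("n_cells_initial must be >= 0 and n_frames >= 1")
        if self.release_rate < 0 or self.spheroid_radius <= 0:
            raise ParameterError("release_rate must be >= 0 and spheroid_radius > 0")
        if self.frame_interval <= 0 or self.speed_mean <= 0 or self.speed_cv < 0:
            raise ParameterError("frame_interval and speed_mean must be > 0, speed_cv >= 0")
        if self.persistence_kappa < 0 or self.fiber_bias_kappa < 0:
            raise ParameterError("concentration parameters must be >= 0")
        if not (0.0 <= self.p_detach <= 1.0):
            raise ParameterError(f"p_detach must be in [0, 1], got {self.p_detach}")
        if self.detach_speed_factor <= 0 or self.cohesion_radius <= 0:
            raise ParameterError("detach_speed_factor and cohesion_radius must be > 0")
        if self.position_noise_sd < 0:
            raise ParameterError("position_noise_sd must be >= 0")
        object.__setattr__(self, "fiber_axis_deg", normalize_axis_deg(self.fiber_axis_deg))


@dataclass
class GroundTruth:
    """Generator-side truth for every emitted observation.

    ``per_observation``: (track_id, frame, true_class) with class in
    {"single", "group"}; ``per_track``: (track_id, true_speed) in um/min
    (the cell's base speed before any detachment scaling).
    """

    per_observation: pd.DataFrame
    per_track: pd.DataFrame
    fiber_axis_deg: float = 90.0
    fiber_bias_kappa: float = 0.0

    def class_lookup(self) -> dict:
        return {(int(t), int(f)): c for t, f, c in
                self.per_observation[["track_id", "frame", "true_class"]].itertuples(index=False)}


def sample_axial_von_mises(kappa: float, axis_deg: float, n: int, rng: np.random.Generator):
    """Draw ``n`` axial von Mises direction angles (degrees, (-180, 180]).

    The orientation is von Mises-distributed on the doubled-angle circle
    (mean 2*axis, concentration ``kappa``), halved, and given a uniformly
    random 180-degree flip — an axial distribution symmetric under
    theta -> theta + 180. ``kappa = 0`` reduces to the uniform distribution.
    The expected alignment order toward ``axis_deg`` is the Bessel ratio
    I1(kappa)/I0(kappa).
    """
    if kappa < 0:
        raise ParameterError(f"kappa must be >= 0, got {kappa}")
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    phi = rng.vonmises(2.0 * np.radians(axis_deg), kappa, size=n)
    theta = np.degrees(phi / 2.0) + 180.0 * rng.integers(0, 2, size=n)
    return normalize_angle_deg(theta)


def _sample_heading(rng, prev_heading_rad, persistence_kappa, fiber_axis_rad, bias_kappa):
    """One heading from persistence x axial-bias (product of circular densities).

    Rejection sampling with the persistence kernel as proposal and acceptance
    probability exp(kappa_b * (cos 2(theta - axis) - 1)) <= 1; exact, and it
    reduces to either kernel when the other concentration is 0.
    """
    two_axis = 2.0 * fiber_axis_rad
    while True:
        if persistence_kappa > 0:
            prop = rng.vonmises(prev_heading_rad, persistence_kappa)
        else:
            prop = rng.uniform(-np.pi, np.pi)
        if bias_kappa == 0:
            return prop
        if rng.uniform() < np.exp(bias_kappa * (np.cos(2.0 * prop - two_axis) - 1.0)):
            return prop


class _Cell:
    __slots__ = ("tid", "rng", "pos", "heading", "speed", "single")

    def __init__(self, tid, seed, spheroid_radius, speed_mu, speed_sigma, rim_angle=None):
        self.tid = tid
        self.rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tid,)))
        if rim_angle is None:
            rim_angle = self.rng.uniform(-np.pi, np.pi)
        self.pos = spheroid_radius * np.array([np.cos(rim_angle), np.sin(rim_angle)])
        self.heading = rim_angle  # initial heading points radially outward
        self.speed = float(np.exp(self.rng.normal(speed_mu, speed_sigma)))
        self.single = False


def simulate_spheroid(config: SimConfig, source_label: str = "simulated") -> tuple[TrackTable, GroundTruth]:
    """Generate a spheroid-outgrowth :class:`TrackTable` and its ground truth.

    Frame 0 emits the initial rim configuration; each later frame applies
    release, heading update, motion, cohesion pull-back, detachment and
    emission with localization noise, in that order. Spot IDs are assigned
    sequentially in (frame, track_id) order.
    """
    cfg = config
    sigma2 = np.log1p(cfg.speed_cv ** 2)
    speed_sigma = float(np.sqrt(sigma2))
    speed_mu = float(np.log(cfg.speed_mean) - sigma2 / 2.0)
    axis_rad = np.radians(cfg.fiber_axis_deg)

    cells: list[_Cell] = []
    for i in range(cfg.n_cells_initial):
        # equally spaced rim positions: a dense, deterministic starting rim
        cells.append(_Cell(i, cfg.seed, cfg.spheroid_radius, speed_mu, speed_sigma,
                           rim_angle=2.0 * np.pi * i / max(cfg.n_cells_initial, 1)))
    next_tid = cfg.n_cells_initial
    release_carry = 0.0

    spot_rows = []
    truth_rows = []
    spot_counter = 0

    def emit(frame):
        nonlocal spot_counter
        for c in cells:
            obs = c.pos
            if cfg.position_noise_sd > 0:
                obs = obs + c.rng.normal(0.0, cfg.position_noise_sd, size=2)
            spot_rows.append((spot_counter, c.tid, float(obs[0]), float(obs[1]), frame))
            truth_rows.append((c.tid, frame, "single" if c.single else "group"))
            spot_counter += 1

    emit(0)
    for frame in range(1, cfg.n_frames):
        # (i) release new cells on the rim
        release_carry += cfg.release_rate
        n_new = int(np.floor(release_carry))
        release_carry -= n_new
        for _ in range(n_new):
            cells.append(_Cell(next_tid, cfg.seed, cfg.spheroid_radius, speed_mu, speed_sigma))
            next_tid += 1

        # (ii) absorbing detachment, decided at the top of the frame so a
        # newly detached cell already breaks away at detached speed within
        # its detachment frame
        for c in cells:
            if not c.single and c.rng.uniform() < cfg.p_detach:
                c.single = True
                # escape heading: radially outward from the spheroid center,
                # the direction detached cells disperse from the outgrowth front
                norm = np.hypot(*c.pos)
                if norm > 0:
                    c.heading = float(np.arctan2(c.pos[1], c.pos[0]))

        # (iii) headings and motion
        for c in cells:
            c.heading = _sample_heading(c.rng, c.heading, cfg.persistence_kappa,
                                        axis_rad, cfg.fiber_bias_kappa)
            factor = cfg.detach_speed_factor if c.single else 1.0
            step = c.speed * factor * cfg.frame_interval
            c.pos = c.pos + step * np.array([np.cos(c.heading), np.sin(c.heading)])

        # cohesion pull-back of group cells, from a post-move snapshot
        group = [c for c in cells if not c.single]
        if len(group) >= 2:
            pts = np.array([c.pos for c in group])
            d, j = cKDTree(pts).query(pts, k=2)
            for i, c in enumerate(group):
                dist = d[i, 1]
                if dist > cfg.cohesion_radius:
                    neighbor = pts[j[i, 1]]
                    c.pos = neighbor + (pts[i] - neighbor) * (cfg.cohesion_radius / dist)

        # (iv) emission with localization noise
        emit(frame)

    spots = pd.DataFrame(spot_rows, columns=["spot_id", "track_id", "x", "y", "frame"])
    calibration = Calibration(pixel_size=0.65, frame_interval=cfg.frame_interval,
                              flip_y=False, fiber_axis_deg=cfg.fiber_axis_deg)
    table = TrackTable(spots=spots, calibration=calibration, source_label=source_label)
    truth = GroundTruth(
        per_observation=pd.DataFrame(truth_rows, columns=["track_id", "frame", "true_class"]),
        per_track=pd.DataFrame(
            sorted((c.tid, c.speed) for c in cells), columns=["track_id", "true_speed"]),
        fiber_axis_deg=cfg.fiber_axis_deg,
        fiber_bias_kappa=cfg.fiber_bias_kappa,
    )
    return table, truth


def render_synthetic_nuclei(
    table: TrackTable,
    image_size: int = 512,
    psf_sd: float = 3.0,
    background_noise: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Rasterize tracks as a synthetic fluorescence-like image stack.

    Per frame: a unit-amplitude Gaussian blob of scale ``psf_sd`` (um) at
    each nucleus position, plus mild Gaussian background noise. Positions
    are mapped to pixels with the table's calibration; nuclei outside the
    field raise a warning and are clipped. Intended as an end-to-end
    fixture for external detection/linking tools — the internal pipeline
    never reads pixels.
    """
    px = table.calibration.pixel_size
    sd_px = psf_sd / px
    frames = table.frames
    n_frames = int(frames.max()) + 1 if len(frames) else 1
    rng = np.random.default_rng(seed)
    stack = rng.normal(0.0, background_noise, size=(n_frames, image_size, image_size)).astype(np.float32)

    xpix = table.spots["x"].to_numpy() / px
    ypix = table.spots["y"].to_numpy() / px
    out_of_field = (xpix < 0) | (xpix >= image_size) | (ypix < 0) | (ypix >= image_size)
    if out_of_field.any():
        warnings.warn(f"{int(out_of_field.sum())} nuclei fall outside the field; clipped")
    xpix = np.clip(xpix, 0, image_size - 1)
    ypix = np.clip(ypix, 0, image_size - 1)

    half = max(int(np.ceil(4 * sd_px)), 2)
    fr = table.spots["frame"].to_numpy()
    for f, cx, cy in zip(fr, xpix, ypix):
        r0, r1 = int(max(np.floor(cy) - half, 0)), int(min(np.floor(cy) + half + 1, image_size))
        c0, c1 = int(max(np.floor(cx) - half, 0)), int(min(np.floor(cx) + half + 1, image_size))
        yy, xx = np.mgrid[r0:r1, c0:c1]
        stack[int(f), r0:r1, c0:c1] += np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sd_px ** 2)).astype(np.float32)
    return stack
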