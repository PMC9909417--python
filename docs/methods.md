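# Methods

## Scope and data model

The package quantifies collective migration from tracker *spot statistics*
tables: per-nucleus positions over time, already detected and linked
upstream. It never touches pixels (the optional synthetic-image renderer
exists only to feed external detectors). Positions are converted to
micrometres on read and frames kept as integers; time in minutes is always
derived as `frame × frame_interval`, never stored, so nothing can drift
under re-calibration. The acquisition cadence the defaults assume is one
frame per 30 min over 24 h (48 frames). One observation per track per frame
is enforced; gaps are allowed (the upstream linker closes detection gaps),
and every step-based quantity uses the true frame difference in its `dt`.

Two export dialects are read: the classic single-header table, and the
newer dialect with auxiliary label/unit rows under the header. Any
contiguous block of rows directly below the header whose frame field is
non-numeric is treated as metadata and skipped — this tolerates both
dialects without a format-version switch. Spots without a track ID
(unlinked detections) are dropped and counted, not treated as errors.

The y-axis convention of image data (y grows downward) is handled by an
explicit `flip_y` calibration flag that negates y on read, rather than a
guess baked into the math; all distances and speeds are
reflection-invariant, so the flag affects only reported angles.
Likewise no re-centering on the spheroid is done: every implemented metric
is translation-invariant, so the tracker's image origin is fine as-is.

## Migration metrics

A *step* is the displacement between consecutive observations of a track:
length `√(dx² + dy²)` µm, duration `dt` min, speed length/`dt`, direction
`atan2(dy, dx)` in degrees, normalized into (−180, 180]. A zero-length step
has no direction: it carries a NaN angle, is excluded from every angular
statistic, and still contributes speed 0 to speed statistics — any other
convention would require inventing an angle.

Per track: accumulated distance (Σ step lengths), Euclidean distance
(|last − first|), `mean_speed = accumulated / elapsed time` with elapsed
time taken from first to last frame (this makes the mean robust to
gap-closed tracks with unequal `dt`, and coincides with the mean of step
speeds when sampling is uniform — the dt-weighted mean of instantaneous
speeds equals `mean_speed` as an exact identity, which the tests assert),
median step speed, the directionality ratio Euclidean/accumulated (NaN for
a track that never moved), and the net direction. "Directionality" is
deliberately split into step angle, net direction and directionality ratio,
because the field uses the one word for all three.

Polar histograms use equal-width half-open bins `[lo, hi)` covering
(−180, 180], last bin closed, angles normalized first — stated so results
are bit-reproducible. Probabilities are counts/n and sum to 1 for non-empty
input.

Directional bias relative to an aligned-fiber substrate is summarized by
the nematic order parameter `S = ⟨cos 2(θ − φ)⟩`, with φ the fiber axis
(an axial quantity normalized into (−90, 90]; the assay convention puts
aligned fibers at ±90°). The doubled angle makes directions axial: adding
180° to any subset of angles leaves S unchanged (property-tested). For an
axial von Mises sample of concentration κ, E[S] = I₁(κ)/I₀(κ); this
Bessel-ratio closed form is the oracle for all bias-recovery tests
(≈ 0.6978 at κ = 2).

Speed–directionality structure is probed by partitioning tracks into four
bins of per-track mean speed. The bin edges default to quantiles (quartile
partition) because no canonical absolute edges exist across cell lines;
explicit edges can be supplied. Bins are half-open with the last closed;
with all speeds tied, every track legitimately lands in one bin.

The instantaneous series aggregates, per frame, all steps *ending* at that
frame: cell count, mean and SEM of speed (n−1 variance; SEM undefined below
two cells), and the mean alignment order of the defined angles. Frames are
the index; conversion to hours is presentation only.

## Single-cell dispersion

Per frame, each nucleus's Euclidean distance to its nearest other nucleus
is computed (cKDTree, k = 2 — an exact method, verified label-for-label
against a hand-written all-pairs oracle); the nucleus is *single* iff that
distance strictly exceeds the threshold, with equality counting as group so
the boundary is reproducible. A lone nucleus is single. The default
threshold is 40 µm, but the value is cell-line-specific and user-set; a
sweep utility reruns the census over a threshold list, and the census is
provably monotone: the single set at a higher threshold is contained in the
single set at any lower one.

Classification is per-frame and memoryless — a detached cell that rejoins
the sheet is group again — matching a frame-loop definition rather than
any hysteresis. Class-split statistics assign each step the class of its
nucleus at the step's *end* frame; the weighted-mean identity
`n_single·mean_single + n_group·mean_group = n_total·mean_all` holds
exactly at every frame and is asserted on random tables.

Overlay rendering draws group nuclei grey and single nuclei red on a white
canvas with a world-to-pixel mapping fixed across frames (global bounding
box + 5% margin), stamping frame index and threshold in a corner. Output is
a lossless PNG sequence (optionally an animated GIF); rendering is fully
deterministic, and the per-frame raster — not a video container — is the
contract.

## Synthetic spheroid outgrowth

The generator is phenomenological: it reproduces the statistical signatures
the measurement code consumes (outward spreading, speed heterogeneity,
axial directional bias, cohesion, detachment, localization noise), not cell
mechanics. No forces, proliferation, death or 3D. Only outgrowing cells are
emitted — the opaque spheroid core is invisible to a tracker in the real
assay too.

Cells start equally spaced on the rim of a disk (radius 150 µm by default)
heading radially outward, and `release_rate` new cells join per frame
(fractional rates accumulate). Per-cell speeds are lognormal with mean
`speed_mean` (default 0.5 µm/min, a realistic scale for motile
breast-carcinoma cells) and CV `speed_cv` (default 0.4): cell-level
heterogeneity with frame-level constancy, chosen so the speed-binned
directionality analysis has real between-cell structure to find.

Each frame a cell's heading combines a persistence kernel (von Mises about
the previous heading, concentration `persistence_kappa`, default 2) with an
axial contact-guidance kernel (axial von Mises toward `fiber_axis_deg`,
concentration `fiber_bias_kappa`, default 0 = isotropic substrate). The two
circular densities multiply; sampling is exact rejection with the
persistence kernel as proposal and acceptance
`exp(κ_b(cos 2(θ − φ) − 1))`, which reduces to either kernel when the
other's concentration is zero. The axial von Mises itself is sampled on the
doubled-angle circle, halved, with a uniformly random 180° flip.

Group cohesion: after all cells move, any group cell farther than
`cohesion_radius` (default 25 µm) from its nearest group neighbor (computed
from a post-move snapshot) is pulled back along that line to the cohesion
radius. This bounds within-group nearest-neighbor spacing near the cohesion
radius (a neighbor's own pull-back can stretch a pair transiently by at
most one step length), keeping the sheet comfortably inside a 40 µm
classification threshold at the default speeds.

Detachment: at the top of each frame, each group cell detaches with
probability `p_detach` (default 0.01/frame). Detachment is absorbing —
singles never rejoin in the *truth*, even though the classifier is
memoryless — keeping ground truth unambiguous. A detaching cell's heading
is re-aimed radially outward from the spheroid center, the direction
detached cells disperse from the outgrowth front, and its speed scales by
`detach_speed_factor` (default 1.5, reflecting the faster single cells seen
on stiff uniform substrates), so it breaks away from the sheet within its
detachment frame rather than lingering at ambiguous distances.

Localization noise (`position_noise_sd`, default 1 µm) is observation-only:
emitted positions are jittered, the dynamics use true positions. Every cell
owns an independent random stream spawned from `(seed, track_id)`, so adding
cells never perturbs other cells' draws and identical configurations are
bit-identical.

Ground truth records the class of every observation and each cell's base
speed. Two recovery caveats the tests respect:

- **Speed recovery** is tested with cohesion effectively disabled: cohesive
  pull-backs shorten realized paths by construction (a real feature of
  confluent motion), so measured mean speed under tight cohesion is biased
  below the sampled per-cell speed. With cohesion off and noise off, the
  per-track measured mean speed equals the sampled speed to machine
  precision.
- **Classifier-vs-truth agreement** is measured under *margin-separated
  geometry*: cohesion (22 µm) plus worst-case pull-back stretch stays below
  the 40 µm threshold, detached cells escape at 5× speed with strong
  persistence (κ = 20), detachment is rare (0.002/frame), and localization
  noise (0.5 µm) is far below the ~5 µm margin. Under these conditions
  agreement exceeds 99% (99.2–99.96% over ten seeds). Without separation —
  dense sheets, slow escape — a memoryless distance threshold *cannot*
  recover the absorbing truth for a single cell that wanders back within
  threshold range; that disagreement is a property of the definitions, not
  a defect, and mirrors how real detached cells re-contacting the sheet
  would be scored frame by frame.

What the generator does **not** emulate: nuclei detection/linking errors
(split or merged tracks), proliferation and death, spatially varying fiber
fields, or 3D motion. Passing tests therefore validate the measurement
definitions and their implementation, not the upstream tracking quality of
real movies.

## Pipeline, determinism and problem sizes

The `analyze` workflow runs read → filter → steps/metrics → instantaneous
series → polar + speed-binned directionality → dispersion (+ optional
sweep) → class split → overlay, writing plain CSV tables and a JSON
manifest (config snapshot, version, input SHA-256, per-stage row counts —
including the structural identity `n_steps = n_spots − n_tracks`, asserted
every run). Nothing timestamped enters any output, so re-running on
identical input is byte-identical; downstream statistics (e.g. the
between-condition t-tests typical of these assays) are left to any external
tool, with an `aggregate` command to concatenate per-spheroid tables under
condition labels.

Default track filtering is intentionally minimal (drop single-observation
tracks only); dead-cell removal is normally done upstream before tracking,
and stricter `min_points` / `min_accumulated_um` thresholds are explicit
user choices.

Verification sizes were chosen to exercise realistic scales while staying
quick on a laptop: oracle comparison over 200 random frames of up to 500
nuclei (bracketing the 200–800 nuclei/frame of real acquisitions),
simulated spheroids of ~100–300 cells over 48 half-hour frames, and ten
independent seeds wherever a stochastic property is averaged.
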