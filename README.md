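# spherotrack

Quantification of collective cell migration from nucleus-tracking tables.

In a spheroid-outgrowth assay, a multicellular cancer spheroid (e.g.
MDA-MB-231) is plated on a 2D substrate — glass, or electrospun fiber mats
with random or aligned fiber orientation — and the Hoechst-labelled nuclei
are imaged every 30 min for about 24 h. An upstream particle tracker
(TrackMate-style: LoG detection, LAP linking) turns the movie into a *spot
statistics* table: one row per nucleus per frame with a spot ID, a track ID,
X/Y position and frame index. `spherotrack` consumes that table and computes
everything downstream:

- **Per-cell migration metrics.** For each track: accumulated distance
  (total path length), Euclidean distance (start-to-end), mean speed
  (accumulated / elapsed time), median step speed, the directionality ratio
  `D = d_euclid / d_accum ∈ [0, 1]`, and the net direction angle. Per step:
  instantaneous speed and direction.
- **Population statistics.** Instantaneous speed time series (mean ± SEM per
  frame), polar probability distributions of motion direction, tracks
  partitioned into four mean-speed bins with per-bin direction distributions
  (speed–directionality correlation), and the nematic alignment order
  parameter `S = ⟨cos 2(θ − φ)⟩` against the fiber axis φ (1 = parallel,
  0 = isotropic, −1 = perpendicular) as a scalar summary of contact
  guidance.
- **Single-cell dispersion.** In every frame, each nucleus is labelled
  *single* (detached) when its nearest-neighbor distance exceeds a user-set
  threshold (default 40 µm; 30/50/100 µm sweeps supported), giving
  single-cell counts and single/total ratios over time, class-split speed
  and directionality, and an overlay rendering (group cells grey, single
  cells red) as a lossless PNG sequence or animated GIF.
- **A synthetic spheroid-outgrowth simulator.** An agent-based generator of
  already-linked tracks — outward spreading, persistent biased random walks,
  axial von Mises contact-guidance bias, loose group cohesion, stochastic
  absorbing detachment, localization noise — with per-observation ground
  truth, so the whole pipeline is testable without microscopy data.

It is aimed at cell-migration labs who already track nuclei and want
reproducible, scriptable downstream numbers instead of spreadsheet work.

## Worked example

Simulate one synthetic spheroid and run the full analysis:

```sh
spherotrack simulate --seed 4 --n-frames 8 --out-tracks demo.csv
# simulated 81 tracks, 564 spots -> demo.csv
spherotrack analyze --tracks demo.csv --out-dir demo_out --sweep 30,50,100
# wrote 10 artifacts to demo_out
```

`demo_out/track_metrics.csv` then starts:

```
track_id,n_points,total_time,accumulated_distance,euclidean_distance,mean_speed,median_speed,directionality_ratio,net_direction_deg
0,8,210,84.76520636,21.04243933,0.4036438398,0.4012356124,0.2482438283,72.60228054
1,8,210,85.41965572,35.02553382,0.4067602653,0.3388732921,0.4100406812,6.009013391
```

Track 0 was observed 8 times over 210 min, crawled 84.8 µm of path but
ended only 21.0 µm from where it started — a directionality ratio of 0.25,
a meandering cell — at a mean speed of 0.40 µm/min. `dispersion.csv` holds
the per-frame census for each threshold:

```
threshold,frame,n_total,n_single,ratio,single_ids
30,0,60,0,0,
30,1,63,0,0,
```

i.e. 60 nuclei in frame 0, none farther than 30 µm from its nearest
neighbor, so no detached single cells yet. The other artifacts are the
steps, the instantaneous series, polar and speed-binned direction tables,
class-split statistics, single-cell angles, overlay frames and a
`manifest.json` recording configuration, input checksum and row counts.

The same operations are available as a library
(`read_spot_table`, `track_metrics`, `dispersion_timeseries`,
`simulate_spheroid`, ...); see the module docstrings and
`docs/methods.md` for the underlying definitions and model.

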