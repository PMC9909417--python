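"""KNN single/group classification, dispersion series, class splits, overlays."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spherotrack import (IntegrityError, ParameterError, classify_frame,
                         dispersion_timeseries, render_overlay,
                         split_metrics_by_class, sweep_table, threshold_sweep)

from conftest import make_table, random_table


def brute_force_labels(points, threshold):
    """All-pairs oracle: single iff every other nucleus is farther than threshold."""
    pts = np.asarray(points, float)
    n = len(pts)
    labels = []
    for i in range(n):
        nn = np.inf
        for j in range(n):
            if i != j:
                nn = min(nn, float(np.hypot(*(pts[i] - pts[j]))))
        labels.append(n == 1 or nn > threshold)
    return np.array(labels)


class TestClassifyFrame:
    def test_three_point_example(self):
        c = classify_frame(np.array([[0, 0], [10, 0], [100, 0]], float), 40.0)
        assert list(c.is_single) == [False, False, True]
        np.testing.assert_allclose(c.nn_distance, [10.0, 10.0, 90.0])

    def test_lone_nucleus_is_single(self):
        c = classify_frame(np.array([[5.0, 5.0]]), 40.0)
        assert c.n_single == 1
        assert np.isnan(c.nn_distance[0])

    def test_boundary_distance_counts_as_group(self):
        c = classify_frame(np.array([[0.0, 0.0], [40.0, 0.0]]), 40.0)
        assert c.n_single == 0

    def test_non_positive_threshold_rejected(self):
        with pytest.raises(ParameterError):
            classify_frame(np.zeros((2, 2)), 0.0)

    def test_matches_all_pairs_oracle_on_random_frames(self):
        rng = np.random.default_rng(100)
        for _ in range(40):
            n = int(rng.integers(1, 120))
            pts = rng.uniform(0, 300, size=(n, 2))
            thr = float(rng.uniform(5, 80))
            c = classify_frame(pts, thr)
            np.testing.assert_array_equal(c.is_single, brute_force_labels(pts, thr))

    def test_nn_symmetric_consistency(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 200, size=(50, 2))
        c = classify_frame(pts, 40.0)
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        np.testing.assert_allclose(c.nn_distance, d.min(axis=1), rtol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_rigid_motion_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        pts = rng.uniform(0, 200, size=(n, 2))
        thr = float(rng.uniform(5, 80))
        base = classify_frame(pts, thr).is_single
        theta = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + rng.uniform(-1000, 1000, 2)
        np.testing.assert_array_equal(classify_frame(moved, thr).is_single, base)
        perm = rng.permutation(n)
        np.testing.assert_array_equal(classify_frame(pts[perm], thr).is_single, base[perm])


class TestDispersionTimeseries:
    def test_two_frame_census(self):
        t = make_table({
            0: [(0, 0.0, 0.0), (1, 1.0, 0.0)],
            1: [(0, 10.0, 0.0), (1, 11.0, 0.0)],
            2: [(0, 5.0, 8.0), (1, 6.0, 8.0)],
            3: [(1, 200.0, 200.0)],
        })
        res = dispersion_timeseries(t, 40.0)
        df = res.to_frame()
        assert df[["frame", "n_total", "n_single"]].values.tolist() == [[0, 3, 0], [1, 4, 1]]
        np.testing.assert_allclose(df["ratio"], [0.0, 0.25])
        assert df.loc[1, "single_ids"] != ""

    def test_cohesive_table_has_no_singles(self):
        t = make_table({k: [(f, 10.0 * k, 1.0 * f) for f in range(5)] for k in range(4)})
        df = dispersion_timeseries(t, 40.0).to_frame()
        assert (df["n_single"] == 0).all()

    def test_threshold_monotonicity_on_random_tables(self):
        for seed in range(10):
            t = random_table(np.random.default_rng(seed), n_tracks=15, box=150.0)
            sweep = threshold_sweep(t, [30.0, 50.0, 100.0])
            for f in t.frames:
                s30 = sweep[30.0].classifications[f].single_ids
                s50 = sweep[50.0].classifications[f].single_ids
                s100 = sweep[100.0].classifications[f].single_ids
                assert s100 <= s50 <= s30

    def test_single_threshold_sweep_matches_timeseries(self):
        t = random_table(np.random.default_rng(2))
        alone = threshold_sweep(t, [40.0])[40.0].to_frame()
        direct = dispersion_timeseries(t, 40.0).to_frame()
        pd.testing.assert_frame_equal(alone, direct)

    def test_sweep_rejects_bad_thresholds(self):
        t = random_table(np.random.default_rng(1))
        with pytest.raises(ParameterError):
            threshold_sweep(t, [])
        with pytest.raises(ParameterError):
            threshold_sweep(t, [30.0, -1.0])

    def test_detachment_rate_raises_single_counts(self):
        from spherotrack import SimConfig, simulate_spheroid
        diffs = []
        for seed in range(5):
            means = {}
            for p in (0.0, 0.02):
                cfg = SimConfig(n_cells_initial=40, release_rate=1.0, n_frames=30,
                                p_detach=p, detach_speed_factor=3.0,
                                persistence_kappa=4.0, cohesion_radius=20.0,
                                position_noise_sd=0.5, seed=seed)
                table, _ = simulate_spheroid(cfg)
                df = dispersion_timeseries(table, 40.0).to_frame()
                means[p] = df["n_single"].mean()
            diffs.append(means[0.02] - means[0.0])
        assert all(d > 0 for d in diffs)


class TestSplitMetricsByClass:
    def test_constructed_single_vs_group_speeds(self):
        # three cohesive tracks at 0.1 um/min, one detached track at 0.4 um/min
        tracks = {k: [(f, 3.0 * f + 10.0 * k, 0.0) for f in range(6)] for k in range(3)}
        tracks[3] = [(f, 12.0 * f, 500.0) for f in range(6)]
        t = make_table(tracks, frame_interval=30.0)
        res = dispersion_timeseries(t, 40.0)
        split = split_metrics_by_class(t, res.classifications)
        by = split.series.set_index(["frame", "cell_class"])
        for f in range(1, 6):
            assert by.loc[(f, "single"), "mean_speed"] == pytest.approx(0.4)
            assert by.loc[(f, "group"), "mean_speed"] == pytest.approx(0.1)

    def test_no_singles_group_series_equals_unsplit(self):
        from spherotrack import instantaneous_series
        t = make_table({k: [(f, 5.0 * k, 2.0 * f) for f in range(6)] for k in range(4)})
        res = dispersion_timeseries(t, 40.0)
        split = split_metrics_by_class(t, res.classifications)
        assert set(split.series["cell_class"]) == {"group"}
        unsplit = instantaneous_series(t)
        merged = split.series.merge(unsplit, on="frame")
        np.testing.assert_allclose(merged["mean_speed_x"], merged["mean_speed_y"])
        np.testing.assert_allclose(merged["n_cells_x"], merged["n_cells_y"])

    def test_weighted_mean_identity_random_tables(self):
        from spherotrack import compute_steps
        for seed in range(5):
            t = random_table(np.random.default_rng(seed), n_tracks=12, box=120.0)
            res = dispersion_timeseries(t, 30.0)
            split = split_metrics_by_class(t, res.classifications)
            steps = compute_steps(t)
            overall = steps.groupby("frame_to")["speed"].agg(["size", "mean"])
            for f, row in overall.iterrows():
                sub = split.series[split.series["frame"] == f]
                total = (sub["n_cells"] * sub["mean_speed"]).sum()
                assert total == pytest.approx(row["size"] * row["mean"], rel=1e-9)

    def test_missing_classification_is_integrity_error(self):
        t = make_table({0: [(0, 0, 0), (1, 3, 4)]})
        res = dispersion_timeseries(t, 40.0)
        res.classifications.pop(1)
        with pytest.raises(IntegrityError):
            split_metrics_by_class(t, res.classifications)


class TestRenderOverlay:
    @pytest.fixture
    def toy(self):
        t = make_table({
            0: [(f, 20.0, 20.0) for f in range(3)],
            1: [(f, 30.0, 20.0) for f in range(3)],
            2: [(f, 200.0, 200.0) for f in range(3)],
        })
        return t, dispersion_timeseries(t, 40.0)

    def test_png_sequence_colors_at_known_coordinates(self, toy, tmp_path):
        from PIL import Image
        t, res = toy
        paths = render_overlay(t, res.classifications, tmp_path / "ov")
        assert len(paths) == 3
        img = np.asarray(Image.open(paths[0]))
        h = img.shape[0]
        df = t.spots
        xmin, xmax = df["x"].min(), df["x"].max()
        ymin, ymax = df["y"].min(), df["y"].max()
        span = max(xmax - xmin, ymax - ymin)
        m = 0.05 * span
        scale = 600 / max(xmax - xmin + 2 * m, ymax - ymin + 2 * m)

        def px(x, y):
            return int((x - (xmin - m)) * scale), int(h - (y - (ymin - m)) * scale)

        cx, cy = px(20.0, 20.0)       # group cell -> grey
        assert tuple(img[cy, cx]) == (150, 150, 150)
        sx, sy = px(200.0, 200.0)     # single cell -> red
        assert tuple(img[sy, sx]) == (214, 39, 40)

    def test_rendering_is_deterministic(self, toy, tmp_path):
        t, res = toy
        p1 = render_overlay(t, res.classifications, tmp_path / "a")
        p2 = render_overlay(t, res.classifications, tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_empty_frame_renders_stamp_only(self, tmp_path):
        t = make_table({0: [(0, 10.0, 10.0)], 1: [(0, 12.0, 10.0)]})
        res = dispersion_timeseries(t, 40.0)
        # synthesize an empty-frame classification
        from spherotrack import FrameClassification
        res.classifications[5] = FrameClassification(
            5, np.array([], dtype=int), np.array([], dtype=bool), np.array([]), 40.0)
        paths = render_overlay(t, res.classifications, tmp_path / "e")
        assert len(paths) == 2

    def test_animated_gif_written(self, toy, tmp_path):
        t, res = toy
        paths = render_overlay(t, res.classifications, tmp_path / "g", fmt="animated-gif")
        assert len(paths) == 1 and paths[0].suffix == ".gif"
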