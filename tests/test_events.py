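import numpy as np
import pandas as pd
import pytest

from peergaze.events import (Fixation, FixationParams, aoi_fixation_time,
                             compute_velocity, condition_summary,
                             detect_fixations)
from peergaze.geometry import ScreenGeometry, deg_per_px, scene_rect_px

GEOM = ScreenGeometry()
PARAMS = FixationParams()
RATE = 300.0
DT = 1000.0 / RATE


def path(*segments):
    """Concatenate (n_samples, x, y) segments into t, x, y arrays."""
    xs, ys = [], []
    for n, x, y in segments:
        xs.append(np.full(n, float(x)))
        ys.append(np.full(n, float(y)))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    t = np.arange(len(x)) * DT
    return t, x, y


class TestVelocity:
    def test_stationary_zero(self):
        t, x, y = path((100, 960, 540))
        assert np.allclose(compute_velocity(t, x, y, GEOM), 0.0)

    def test_constant_drift_closed_form(self):
        # 1 px/sample at 300 Hz -> deg_per_px * 300 deg/s
        n = 100
        t = np.arange(n) * DT
        x = 500.0 + np.arange(n)
        y = np.full(n, 540.0)
        v = compute_velocity(t, x, y, GEOM)
        expected = deg_per_px(GEOM) * RATE
        assert np.allclose(v, expected, rtol=1e-9)
        assert expected == pytest.approx(8.15, abs=0.05)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        n = 200
        t = np.arange(n) * DT
        x = rng.uniform(0, 1920, n)
        y = rng.uniform(0, 1080, n)
        v1 = compute_velocity(t, x, y, GEOM)
        v2 = compute_velocity(t, x + 137.0, y - 55.0, GEOM)
        assert np.allclose(v1, v2)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            compute_velocity(np.array([0.0, DT]), np.zeros(2), np.zeros(2), GEOM)


def brute_force_fixations(t, x, y, params, geom):
    """Independent per-sample re-implementation of the detection contract:
    velocity gate, greedy centroid-update dispersion split, duration gate."""
    v = compute_velocity(t, x, y, geom)
    disp_px = params.dispersion_threshold_deg / deg_per_px(geom)
    cand = v < params.velocity_threshold_deg_s
    groups = []
    i = 0
    n = len(t)
    while i < n:
        if not cand[i]:
            i += 1
            continue
        j = i
        members = []
        while j < n and cand[j]:
            trial = members + [j]
            cx = np.mean([x[m] for m in trial])
            cy = np.mean([y[m] for m in trial])
            if members and np.hypot(x[j] - cx, y[j] - cy) > disp_px:
                groups.append(members)
                members = [j]
            else:
                members = trial
            j += 1
        groups.append(members)
        i = j
    out = []
    for g in groups:
        if len(g) >= 2 and t[g[-1]] - t[g[0]] >= params.min_duration_ms:
            out.append((t[g[0]], t[g[-1]]))
    return out


class TestDetector:
    def test_single_stationary_episode(self):
        n = 90  # 300 ms
        t, x, y = path((n, 960, 540))
        fx = detect_fixations(t, x, y, PARAMS, GEOM)
        assert len(fx) == 1
        assert fx[0].duration_ms == pytest.approx(300.0, abs=7.0)

    def test_short_episode_rejected(self):
        # 60 ms stationary between two fast saccade sweeps
        sweep = 300.0  # px/sample, far above threshold
        n_s = 18  # 60 ms
        xs = np.concatenate([
            np.arange(0, 10) * sweep,
            np.full(n_s, 10 * sweep),
            10 * sweep + np.arange(1, 11) * sweep])
        ys = np.full(len(xs), 540.0)
        t = np.arange(len(xs)) * DT
        fx = detect_fixations(t, xs, ys, PARAMS, GEOM)
        assert fx == []

    def test_dispersion_splits_slow_drift(self):
        """Two 200 ms episodes 5 deg apart joined by sub-threshold drift."""
        sep_px = 5.0 / deg_per_px(GEOM)
        drift_speed = 60.0  # deg/s, below the 75 deg/s gate
        px_per_sample = drift_speed / RATE / deg_per_px(GEOM)
        n_drift = int(np.ceil(sep_px / px_per_sample))
        x = np.concatenate([
            np.full(60, 500.0),
            500.0 + (np.arange(1, n_drift + 1)) * px_per_sample,
            np.full(60, 500.0 + sep_px)])
        y = np.full(len(x), 540.0)
        t = np.arange(len(x)) * DT
        fx = detect_fixations(t, x, y, PARAMS, GEOM)
        assert len(fx) >= 2
        assert abs(fx[0].centroid_px[0] - fx[-1].centroid_px[0]) > sep_px * 0.8

    def test_emitted_fixations_verify_their_invariants(self):
        rng = np.random.default_rng(7)
        k = deg_per_px(GEOM)
        for _ in range(20):
            segs = []
            xpos = 600.0
            for _ in range(5):
                segs.append((int(rng.integers(20, 120)), xpos,
                             540.0 + rng.uniform(-100, 100)))
                xpos += rng.uniform(150, 400)
            t, x, y = path(*segs)
            x += rng.normal(0, 3.0, len(x))
            y += rng.normal(0, 3.0, len(y))
            for f in detect_fixations(t, x, y, PARAMS, GEOM):
                assert f.duration_ms >= PARAMS.min_duration_ms
                assert f.max_dispersion_deg <= PARAMS.dispersion_threshold_deg + 1e-9

    def test_matches_brute_force_oracle_on_random_paths(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            segs = [(int(rng.integers(10, 100)),
                     rng.uniform(400, 1500), rng.uniform(200, 900))
                    for _ in range(6)]
            t, x, y = path(*segs)
            x = x + rng.normal(0, 5.0, len(x))
            y = y + rng.normal(0, 5.0, len(y))
            got = [(f.onset_ms, f.offset_ms)
                   for f in detect_fixations(t, x, y, PARAMS, GEOM)]
            expected = brute_force_fixations(t, x, y, PARAMS, GEOM)
            assert got == pytest.approx(expected)


class TestAOITime:
    AOIS = {1: [(100.0, 100.0, 200.0, 150.0)], 2: []}

    def _fix(self, onset, offset, x_scene, y_scene):
        ox, oy = scene_rect_px(GEOM)[:2]
        return Fixation(onset, offset, (ox + x_scene, oy + y_scene), 10, 0.5)

    def test_fixation_inside_rect_counted(self):
        f = self._fix(1000.0, 2000.0, 200.0, 175.0)
        tm = aoi_fixation_time([f], self.AOIS, 1, (0.0, 5000.0), GEOM)
        assert tm.total_aoi_fixation_ms == pytest.approx(1000.0)

    def test_outside_aois_zero(self):
        f = self._fix(1000.0, 2000.0, 900.0, 600.0)
        tm = aoi_fixation_time([f], self.AOIS, 1, (0.0, 5000.0), GEOM)
        assert tm.total_aoi_fixation_ms == 0.0

    def test_straddling_fixation_clipped(self):
        f = self._fix(4000.0, 6500.0, 200.0, 175.0)
        tm = aoi_fixation_time([f], self.AOIS, 1, (0.0, 5000.0), GEOM)
        assert tm.total_aoi_fixation_ms == pytest.approx(1000.0)

    def test_unknown_scene_errors(self):
        with pytest.raises(KeyError):
            aoi_fixation_time([], self.AOIS, 99, (0.0, 5000.0), GEOM)

    def test_totals_never_exceed_window(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            fixes = []
            t0 = 0.0
            while t0 < 6000:
                dur = rng.uniform(75, 2500)
                fixes.append(self._fix(t0, t0 + dur, rng.uniform(0, 1200),
                                       rng.uniform(0, 750)))
                t0 += dur + rng.uniform(10, 50)
            tm = aoi_fixation_time(fixes, self.AOIS, 1, (0.0, 5000.0), GEOM)
            assert 0.0 <= tm.total_aoi_fixation_ms <= 5000.0

    def test_membership_matches_point_in_rect_oracle(self):
        rng = np.random.default_rng(2)
        ox, oy = scene_rect_px(GEOM)[:2]
        for _ in range(100):
            rects = [(rng.uniform(0, 1000), rng.uniform(0, 600),
                      rng.uniform(50, 200), rng.uniform(50, 150))
                     for _ in range(rng.integers(1, 4))]
            aois = {1: rects}
            px, py = rng.uniform(0, 1200), rng.uniform(0, 750)
            f = self._fix(0.0, 1000.0, px, py)
            tm = aoi_fixation_time([f], aois, 1, (0.0, 5000.0), GEOM)
            inside = any(rx <= px < rx + rw and ry <= py < ry + rh
                         for rx, ry, rw, rh in rects)
            assert (tm.total_aoi_fixation_ms > 0) == inside


class TestConditionSummary:
    def _tables(self):
        design = pd.DataFrame([
            {"trial_id": f"p01_t{i}", "participant_id": "p01",
             "perspective": "self" if i % 2 else "other",
             "valence": "positive" if i < 3 else "negative"}
            for i in range(1, 5)])
        metrics = pd.DataFrame([
            {"trial_id": f"p01_t{i}",
             "total_aoi_fixation_ms": 1200.0 if i % 2 else 800.0}
            for i in range(1, 5)])
        return metrics, design

    def test_cell_means(self):
        metrics, design = self._tables()
        out = condition_summary(metrics, design)
        self_rows = out[out["perspective"] == "self"]
        other_rows = out[out["perspective"] == "other"]
        assert (self_rows["mean_aoi_fixation_ms"] == 1200.0).all()
        assert (other_rows["mean_aoi_fixation_ms"] == 800.0).all()

    def test_grand_mean_is_trial_weighted_cell_mean(self):
        metrics, design = self._tables()
        out = condition_summary(metrics, design)
        joined = metrics.merge(design, on="trial_id")
        counts = joined.groupby(["participant_id", "perspective", "valence"])\
            .size().reset_index(name="n")
        merged = out.merge(counts,
                           on=["participant_id", "perspective", "valence"])
        grand = (merged["mean_aoi_fixation_ms"] * merged["n"]).sum() / merged["n"].sum()
        assert grand == pytest.approx(metrics["total_aoi_fixation_ms"].mean())
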