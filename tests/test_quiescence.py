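import numpy as np
import pytest

from conftest import brute_force_peaks, brute_force_runs
from wormq import (Bout, BoutSet, align_to_onsets, detect_bouts,
                   detect_rim_inactivity, detect_sleep, find_peaks_prominence,
                   fraction_in_bouts, get_preset, minmax_normalize,
                   smooth_local_linear)
from wormq.core_io import DetectionParams, Trace


def wls_oracle(values, window, i, valid):
    """Per-point tricube weighted least squares, coded independently."""
    n = len(values)
    k = min(window, n)
    start = min(max(i - (k - 1) // 2, 0), n - k)
    idx = np.arange(start, start + k)
    d = np.abs(idx - i).astype(float)
    dmax = d.max() if d.max() > 0 else 1.0
    w = (1 - (d / dmax) ** 3) ** 3
    w = w * valid[idx]
    X = np.column_stack([np.ones(k), idx.astype(float)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], values[idx] * sw, rcond=None)
    return coef[0] + coef[1] * i


class TestSmoother:
    def test_constant_series_unchanged(self):
        v = np.full(50, 3.7)
        np.testing.assert_allclose(smooth_local_linear(v, 30), v, atol=1e-9)

    def test_linear_ramp_unchanged(self):
        v = np.linspace(-2, 5, 80)
        np.testing.assert_allclose(smooth_local_linear(v, 30), v, atol=1e-9)

    def test_white_noise_variance_reduced(self, rng):
        v = rng.normal(size=500)
        s = smooth_local_linear(v, 30)
        assert s.var() < v.var()

    @pytest.mark.parametrize("window", [5, 7, 30])
    def test_matches_wls_oracle(self, rng, window):
        for _ in range(5):
            n = int(rng.integers(window + 5, 120))
            v = rng.normal(size=n)
            valid = rng.random(n) > 0.1
            if valid.sum() <= window:
                valid[:] = True
            s = smooth_local_linear(v, window, valid=valid)
            for i in rng.integers(0, n, size=15):
                i = int(i)
                # the WLS oracle covers the generic case; windows with fewer
                # than two positive-weight valid points fall back to the
                # weighted mean and are exercised by dedicated tests
                k = min(window, n)
                start = min(max(i - (k - 1) // 2, 0), n - k)
                idx = np.arange(start, start + k)
                d = np.abs(idx - i).astype(float)
                w = (1 - (d / max(d.max(), 1.0)) ** 3) ** 3 * valid[idx]
                if (w > 0).sum() < 2:
                    continue
                expected = wls_oracle(v, window, i, valid)
                assert s[i] == pytest.approx(expected, abs=1e-8)

    def test_moving_method_is_window_mean(self, rng):
        v = rng.normal(size=60)
        s = smooth_local_linear(v, 7, method="moving")
        # interior point: plain mean of the 7 nearest values
        assert s[30] == pytest.approx(v[27:34].mean())

    def test_window_larger_than_valid_length_errors(self):
        with pytest.raises(ValueError, match="window"):
            smooth_local_linear(np.arange(10.0), 11)

    def test_window_one_is_identity(self, rng):
        v = rng.normal(size=20)
        np.testing.assert_array_equal(smooth_local_linear(v, 1), v)


class TestMinmaxNormalize:
    def test_simple_arithmetic(self):
        np.testing.assert_allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])),
                                   [0.0, 0.5, 1.0])

    def test_affine_invariance(self, rng):
        v = rng.normal(size=40)
        np.testing.assert_allclose(minmax_normalize(v),
                                   minmax_normalize(2.5 * v + 7.0), atol=1e-12)

    def test_constant_series_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.full(10, 5.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_bruteforce_with_invalid_frames(self, rng):
        v = rng.uniform(-3, 9, 50)
        valid = rng.random(50) > 0.2
        out = minmax_normalize(v, valid=valid)
        lo, hi = v[valid].min(), v[valid].max()
        np.testing.assert_allclose(out[valid], (v[valid] - lo) / (hi - lo))
        assert np.all(np.isnan(out[~valid]))


def scan_bouts_oracle(values, valid, threshold, direction, min_frames):
    """Brute-force run-length scanner, written independently of detect_bouts."""
    if direction == "below":
        state = [bool(ok and x < threshold) for x, ok in zip(values, valid)]
    else:
        state = [bool(ok and x > threshold) for x, ok in zip(values, valid)]
    return [(s, e) for s, e in brute_force_runs(state) if e - s >= min_frames]


class TestDetectBouts:
    def test_preset_forced_single_bout(self):
        v = np.ones(100)
        v[40:58] = 0.0  # 18 frames at dt=10 -> 180 s
        bs = detect_bouts(v, get_preset("calcium_20x"), dt=10.0)
        assert [(b.start_index, b.end_index) for b in bs] == [(40, 58)]
        assert bs.bouts[0].duration == 180.0

    def test_17_frames_is_below_min_duration(self):
        v = np.ones(100)
        v[40:57] = 0.0
        bs = detect_bouts(v, get_preset("calcium_20x"), dt=10.0)
        assert len(bs) == 0

    def test_threshold_is_strict(self):
        v = np.full(100, 0.10)  # exactly at threshold: not below
        bs = detect_bouts(v, get_preset("calcium_20x"), dt=10.0)
        assert len(bs) == 0

    def test_invalid_frames_break_runs(self):
        v = np.zeros(40)
        valid = np.ones(40, bool)
        valid[20] = False
        bs = detect_bouts(v, get_preset("calcium_20x"), dt=10.0, valid=valid)
        assert [(b.start_index, b.end_index) for b in bs] == [(0, 20), (21, 40)]

    def test_matches_run_scan_oracle(self, rng):
        presets = [get_preset(n) for n in
                   ("calcium_20x", "calcium_10x", "dic_20x", "neuronal")]
        for _ in range(100):
            n = int(rng.integers(30, 200))
            dt = float(rng.choice([3.0, 5.0, 10.0]))
            v = np.where(rng.random(n) < 0.4, rng.uniform(0, 0.25, n),
                         rng.uniform(0, 1, n))
            valid = rng.random(n) > 0.05
            for params in presets:
                min_frames = int(np.ceil(params.min_duration / dt - 1e-9))
                expected = scan_bouts_oracle(v, valid, params.threshold,
                                             params.direction, min_frames)
                bs = detect_bouts(v, params, dt, valid=valid)
                assert [(b.start_index, b.end_index) for b in bs] == expected

    def test_monotonicity_in_min_duration_and_threshold(self, rng):
        v = rng.uniform(0, 1, 300)
        base = DetectionParams("p", 1, 0.3, 60.0)
        longer = DetectionParams("p", 1, 0.3, 120.0)
        higher = DetectionParams("p", 1, 0.5, 60.0)
        b0 = detect_bouts(v, base, 10.0)
        assert len(detect_bouts(v, longer, 10.0)) <= len(b0)
        assert detect_bouts(v, higher, 10.0).total_duration >= b0.total_duration


class TestFindPeaks:
    def test_single_triangle_peak(self):
        v = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        ps = find_peaks_prominence(v, 0.2)
        assert list(ps.indices) == [2]
        assert ps.prominences[0] == pytest.approx(1.0)

    def test_subthreshold_bump_excluded(self):
        v = np.array([0.0, 0.15, 0.0])
        assert len(find_peaks_prominence(v, 0.2)) == 0

    def test_plateau_reports_leftmost_index(self):
        v = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        ps = find_peaks_prominence(v, 0.5)
        assert list(ps.indices) == [1]

    def test_matches_bruteforce_prominence_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(10, 120))
            v = np.round(rng.normal(size=n).cumsum(), 2)  # rounding makes ties
            pmin = float(rng.uniform(0.1, 1.0))
            got = find_peaks_prominence(v, pmin)
            expected = brute_force_peaks(v, pmin)
            assert list(got.indices) == [i for i, _ in expected]
            np.testing.assert_allclose(got.prominences,
                                       [p for _, p in expected], atol=1e-9)


class TestRimInactivity:
    def test_flat_series_one_full_bout(self):
        v = np.full(60, 1.0)
        bs = detect_rim_inactivity(v, dt=10.0)
        assert [(b.start_index, b.end_index) for b in bs] == [(0, 60)]

    def test_frequent_peaks_no_inactivity(self):
        # prominent peak every 120 s: every gap < 300 s
        t = np.arange(200)
        v = np.where(t % 12 == 6, 1.5, 1.0).astype(float)
        bs = detect_rim_inactivity(v, dt=10.0, smooth_window=1, min_prominence=0.2)
        assert len(bs) == 0

    def test_short_series_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            bs = detect_rim_inactivity(np.ones(10), dt=10.0)
        assert len(bs) == 0

    def test_matches_complement_scanner(self, rng):
        for _ in range(30):
            n = int(rng.integers(60, 300))
            v = np.abs(rng.normal(size=n)).cumsum() * 0.01 + \
                rng.uniform(0.3, 1.2) * (rng.random(n) < 0.05)
            dt = 10.0
            bs = detect_rim_inactivity(v, dt=dt, smooth_window=5,
                                       min_prominence=0.2)
            # oracle: smooth, find peaks, scan the complement
            s = smooth_local_linear(v, 5)
            peak_idx = set(find_peaks_prominence(s, 0.2).indices.tolist())
            free = [i not in peak_idx for i in range(n)]
            expected = [(a, b) for a, b in brute_force_runs(free) if b - a >= 30]
            assert [(b.start_index, b.end_index) for b in bs] == expected


class TestAlignToOnsets:
    def _boutset(self, intervals, n, dt=10.0, label="mobility_quiescence"):
        return BoutSet("a", label, [Bout(s, e, dt, label) for s, e in intervals],
                       n * dt)

    def test_square_wave_step_at_onset(self):
        dt, n = 10.0, 600
        v = np.ones(n)
        intervals = [(120 + 60 * k, 150 + 60 * k) for k in range(7)]
        for s, e in intervals:
            v[s:e] = 0.0
        bs = self._boutset(intervals, n, dt)
        ens = align_to_onsets(v, bs, pre=180, post=180, dt=dt)
        assert ens.n_bouts == len(intervals)
        mean = ens.mean()
        assert np.all(mean[ens.relative_time < 0] == 1.0)
        assert np.all(mean[(ens.relative_time >= 0) & (ens.relative_time < 300)] == 0.0)

    def test_insufficient_history_excluded(self):
        bs = self._boutset([(5, 40)], 100)
        ens = align_to_onsets(np.ones(100), bs, pre=180, post=180, dt=10.0)
        assert ens.n_bouts == 0

    def test_other_bout_in_prewindow_excluded(self):
        bs = self._boutset([(30, 40), (50, 80)], 200)
        ens = align_to_onsets(np.ones(200), bs, pre=180, post=180, dt=10.0)
        # second bout's 18-frame pre-window [32, 50) overlaps the first bout,
        # so only the first bout is eligible
        assert ens.n_bouts == 1

    def test_invalid_frame_in_prewindow_excluded(self):
        valid = np.ones(200, bool)
        valid[40] = False
        bs = self._boutset([(50, 90)], 200)
        ens = align_to_onsets(np.ones(200), bs, pre=180, post=180, dt=10.0,
                              valid=valid)
        assert ens.n_bouts == 0

    def test_matches_index_arithmetic_oracle(self, rng):
        for _ in range(30):
            n = 400
            dt = 10.0
            v = rng.normal(size=n)
            edges = np.sort(rng.choice(np.arange(n), size=10, replace=False))
            intervals = [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])
                         if e > s + 1]
            # enforce the >=1-frame separation BoutSet demands
            intervals = [iv for i, iv in enumerate(intervals)
                         if i == 0 or iv[0] > intervals[i - 1][1]]
            valid = rng.random(n) > 0.05
            bs = self._boutset(intervals, n, dt)
            pre_f, post_f = 18, 30
            ens = align_to_onsets(v, bs, pre=180, post=300, dt=dt, valid=valid)
            in_bout = np.zeros(n, bool)
            for s, e in intervals:
                in_bout[s:e] = True
            expected_rows = []
            for s, e in intervals:
                lo, hi = s - pre_f, s + post_f
                if lo < 0 or hi > n:
                    continue
                if in_bout[lo:s].any() or not valid[lo:s].all():
                    continue
                expected_rows.append(v[lo:hi])
            assert ens.n_bouts == len(expected_rows)
            if expected_rows:
                np.testing.assert_array_equal(ens.snippets, np.vstack(expected_rows))

    def test_paired_pre_post_summary(self):
        bs = self._boutset([(100, 150)], 400)
        v = np.ones(400)
        v[100:] = 0.25
        ens = align_to_onsets(v, bs, pre=180, post=180, dt=10.0)
        pre, post = ens.paired_pre_post()
        assert pre[0] == pytest.approx(1.0)
        assert post[0] == pytest.approx(0.25)


class TestFractionInBouts:
    def _boutset(self, intervals, n, dt=10.0):
        return BoutSet("a", "mobility_quiescence",
                       [Bout(s, e, dt, "mobility_quiescence") for s, e in intervals],
                       n * dt)

    def test_no_bouts_zero(self):
        assert fraction_in_bouts(self._boutset([], 100)) == 0.0

    def test_full_cover_one(self):
        assert fraction_in_bouts(self._boutset([(0, 100)], 100)) == 1.0

    def test_zero_length_interval_errors(self):
        with pytest.raises(ValueError):
            fraction_in_bouts(self._boutset([], 100), (50.0, 50.0))

    def test_whole_trace_equals_duration_ratio(self, rng):
        intervals = [(10, 30), (50, 90), (95, 99)]
        bs = self._boutset(intervals, 100)
        total = sum((e - s) * 10.0 for s, e in intervals)
        assert fraction_in_bouts(bs) == pytest.approx(total / 1000.0)

    def test_matches_frame_membership_oracle(self, rng):
        for _ in range(20):
            n = 200
            edges = np.sort(rng.choice(np.arange(n), size=8, replace=False))
            intervals = [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])
                         if e > s]
            intervals = [iv for i, iv in enumerate(intervals)
                         if i == 0 or iv[0] > intervals[i - 1][1]]
            bs = self._boutset(intervals, n)
            a, b = sorted(rng.choice(np.arange(1, n), size=2, replace=False))
            frac = fraction_in_bouts(bs, (a * 10.0, b * 10.0))
            member = np.zeros(n, bool)
            for s, e in intervals:
                member[s:e] = True
            assert frac == pytest.approx(member[a:b].mean())


class TestDetectSleep:
    def _trace(self, speed, dt=10.0, valid=None):
        return Trace(animal_id="a", strain="wt", dt=dt,
                     t=np.arange(speed.size) * dt, speed=speed, valid=valid)

    def test_planted_long_episodes_recovered_with_smoother_offset(self):
        """Noiseless square-wave: each planted long episode maps to exactly
        one detected bout whose boundaries carry the smoother's constant
        step-response offset (8 frames at window 30 / threshold 0.10)."""
        n, dt = 2000, 10.0
        speed = np.full(n, 2.0)
        planted = [(200, 260), (700, 790), (1300, 1390)]
        for s, e in planted:
            speed[s:e] = 0.0
        bs = detect_sleep(self._trace(speed, dt), "calcium_20x")
        assert len(bs) == len(planted)
        for (s, e), b in zip(planted, bs):
            assert b.start_index == s + 8
            assert b.end_index == e - 8

    def test_all_mobile_recording_empty(self, rng):
        speed = np.abs(rng.normal(2.0, 0.3, size=1000))
        bs = detect_sleep(self._trace(speed), "calcium_20x")
        assert len(bs) == 0

    def test_scale_invariance_of_detection(self, rng):
        speed = np.abs(rng.normal(2.0, 0.3, size=1500))
        speed[400:500] *= 0.02
        tr1 = self._trace(speed)
        tr2 = self._trace(2.0 * speed)
        b1 = detect_sleep(tr1, "calcium_20x")
        b2 = detect_sleep(tr2, "calcium_20x")
        assert [(b.start_index, b.end_index) for b in b1] == \
               [(b.start_index, b.end_index) for b in b2]

    def test_rejects_prominence_preset(self):
        with pytest.raises(ValueError, match="threshold preset"):
            detect_sleep(self._trace(np.ones(100)), "rim_peaks")
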