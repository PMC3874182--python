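"""Greedy segmenter, its residual-structure score, and the DP oracle."""

import itertools

import numpy as np
import pytest

import smtrace as sm
from smtrace.segmentation import _ols


def normal_equation_fit(t, y):
    """Closed-form OLS via the normal equations (independent oracle)."""
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]


class TestFitLine:
    def test_exact_line_zero_residuals(self):
        t = np.arange(0, 10, 0.2)
        tr = sm.Trace(t, 3 + 0.5 * t, np.full_like(t, 25.0))
        slope, intercept, resid = sm.fit_line(tr, 0, len(t) - 1)
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert intercept == pytest.approx(3.0, abs=1e-12)
        assert np.max(np.abs(resid)) < 1e-12

    def test_symmetric_v_has_zero_slope(self):
        t = np.arange(0, 10.2, 0.2)
        y = np.abs(t - 5.0)
        tr = sm.Trace(t, y, np.full_like(t, 25.0))
        slope, _, _ = sm.fit_line(tr, 0, len(t) - 1)
        assert slope == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 20, 0.2)
        y = rng.normal(size=len(t))
        tr = sm.Trace(t, y, np.full_like(t, 25.0))
        slope, intercept, _ = sm.fit_line(tr, 5, 80)
        s2, i2 = normal_equation_fit(t[5:81], y[5:81])
        assert slope == pytest.approx(s2, abs=1e-10)
        assert intercept == pytest.approx(i2, abs=1e-10)

    def test_too_few_samples_rejected(self):
        t = np.arange(0, 1, 0.2)
        tr = sm.Trace(t, t, np.full_like(t, 25.0))
        with pytest.raises(ValueError):
            sm.fit_line(tr, 2, 2)


class TestSegmentScore:
    def test_zero_residuals_score_zero(self):
        assert sm.segment_score(np.zeros(50)) == 0.0

    def test_scales_linearly_with_residual_magnitude(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=200)
        e -= e.mean()
        assert sm.segment_score(2 * e) == pytest.approx(2 * sm.segment_score(e), rel=1e-9)

    def test_structured_residuals_score_higher_than_white(self):
        rng = np.random.default_rng(2)
        n = 200
        white = rng.normal(size=n)
        white -= white.mean()
        x = np.linspace(-1, 1, n)
        parab = x**2 - np.mean(x**2)
        parab *= np.sqrt(np.mean(white**2) / np.mean(parab**2))  # equal RMS
        assert sm.segment_score(parab) > 3 * sm.segment_score(white)

    def test_requires_three_residuals(self):
        with pytest.raises(ValueError):
            sm.segment_score(np.array([1.0, -1.0]))

    def test_literal_variant_is_degenerate_for_ols_residuals(self):
        # intercept-OLS residuals sum to zero and their biased
        # autocorrelations sum to exactly -1/2, so the verbatim score
        # |sum(e)|/n * sum(rho) vanishes for every candidate interval
        rng = np.random.default_rng(3)
        t = np.arange(0, 30, 0.2)
        y = 5 + 0.3 * t + rng.normal(0, 5, len(t))
        tr = sm.Trace(t, y, np.full_like(t, 25.0))
        _, _, resid = sm.fit_line(tr, 0, len(t) - 1)
        from smtrace.segmentation import _abs_autocorr

        _, signed = _abs_autocorr(resid)
        assert signed == pytest.approx(-0.5, abs=1e-9)
        assert sm.segment_score(resid, mode="literal") == pytest.approx(0.0, abs=1e-12)

    def test_score_invariant_to_offset_and_time_shift(self, piecewise_trace_factory):
        tr, _ = piecewise_trace_factory([30.0], [0.5], sigma=4.0, seed=9)
        p = sm.SegmentationParams(settle=0, overlap=0)
        seg1 = sm.best_segment_from(tr, 0, p)
        shifted = sm.Trace(tr.time + 100.0, tr.extension + 250.0, tr.force)
        seg2 = sm.best_segment_from(shifted, 0, p)
        assert seg1.score == pytest.approx(seg2.score, rel=1e-9)
        assert seg1.slope == pytest.approx(seg2.slope, rel=1e-9)


class TestBestSegment:
    def test_noiseless_line_returns_full_window(self, piecewise_trace_factory):
        tr, _ = piecewise_trace_factory([40.0], [0.3])
        seg = sm.best_segment_from(tr, 0, sm.SegmentationParams(settle=0))
        assert seg.t_end == pytest.approx(tr.time[-1])
        assert seg.score < 1e-15

    def test_noiseless_knot_found_within_one_sample(self, piecewise_trace_factory):
        tr, knots = piecewise_trace_factory([60.0, 40.0], [0.0, 0.5])
        seg = sm.best_segment_from(tr, 100, sm.SegmentationParams(settle=0))  # from 20 s
        assert abs(seg.t_end - knots[0]) <= tr.dt + 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_white_noise_slope_within_two_se_of_zero(self, seed, piecewise_trace_factory):
        tr, _ = piecewise_trace_factory([60.0], [0.0], sigma=10.0, seed=seed)
        seg = sm.best_segment_from(tr, 0, sm.SegmentationParams(settle=0))
        assert abs(seg.slope) < 2 * seg.slope_se

    def test_insufficient_data_rejected(self, piecewise_trace_factory):
        tr, _ = piecewise_trace_factory([10.0], [0.0])
        with pytest.raises(ValueError):
            sm.best_segment_from(tr, len(tr.time) - 3, sm.SegmentationParams(settle=0))


class TestGreedy:
    def test_three_piece_recovery_matches_dp(self, piecewise_trace_factory):
        tr, knots = piecewise_trace_factory([10.0, 8.0, 12.0], [0.0, 2.0, 0.0])
        p = sm.SegmentationParams(settle=0, overlap=0)
        greedy = sm.segment_trace(tr, p)
        dp = sm.dp_segment(tr, p, max_segments=5)
        assert len(greedy.segments) == 3
        assert len(dp.segments) == 3
        for res in (greedy, dp):
            ends = [s.t_end for s in res.segments[:-1]]
            for e, k in zip(ends, knots):
                assert abs(e - k) <= tr.dt + 1e-9

    def test_control_trace_slopes_near_zero(self):
        trace = sm.simulate_control_trace(
            sm.standard_binding_protocol(56.0), sm.NoiseModel(), seed=8
        )
        res = sm.segment_trace(trace)
        assert res.segments
        for seg in res.segments:
            assert abs(seg.slope) < 2.5 * seg.slope_se

    def test_consecutive_segments_overlap_at_most_half_second(self):
        trace, _ = sm.simulate_binding_trace(
            sm.standard_binding_protocol(56.0),
            sm.FilamentSpec(700),
            sm.BindingKinetics(),
            sm.NoiseModel(),
            seed=2,
        )
        res = sm.segment_trace(trace)
        for a, b in zip(res.segments, res.segments[1:]):
            if b.t_start < a.t_end:  # same analysis window
                assert a.t_end - b.t_start <= 0.5 + 1e-9

    def test_window_coverage(self):
        """Segments + skips + small gaps tile each analysis window."""
        trace, _ = sm.simulate_binding_trace(
            sm.standard_binding_protocol(56.0),
            sm.FilamentSpec(700),
            sm.BindingKinetics(),
            sm.NoiseModel(),
            seed=13,
        )
        p = sm.SegmentationParams()
        res = sm.segment_trace(trace, p)
        for w0, w1 in res.analyzed_windows:
            inside = [s for s in res.segments if s.t_start >= w0 - 1e-9 and s.t_end <= w1 + 1e-9]
            assert inside, f"no segments in window {w0}-{w1}"
            assert inside[0].t_start == pytest.approx(w0, abs=trace.dt)
            assert inside[-1].t_end == pytest.approx(w1, abs=trace.dt)
            covered = inside[0].t_end
            for seg in inside[1:]:
                assert seg.t_start - covered <= p.skip_max + 1e-9
                covered = max(covered, seg.t_end)

    def test_short_noise_burst_is_skipped_and_logged(self, piecewise_trace_factory):
        tr, _ = piecewise_trace_factory([60.0], [0.0], sigma=2.0, seed=4)
        y = tr.extension.copy()
        burst = slice(150, 153)  # 0.6 s of wild samples at t=30
        y[burst] += 60.0
        noisy = sm.Trace(tr.time, y, tr.force)
        res = sm.segment_trace(noisy, sm.SegmentationParams(settle=0))
        assert res.skipped
        s0, s1 = res.skipped[0]
        assert 29.0 <= s0 <= 31.0
        assert s1 - s0 <= 1.0 + 1e-9

    def test_estimator_api(self):
        trace = sm.simulate_control_trace(
            sm.standard_binding_protocol(56.0), sm.NoiseModel(), seed=0
        )
        est = sm.GreedySegmenter(min_len=4.0)
        assert est.get_params()["min_len"] == 4.0
        out = est.fit_transform(trace)
        assert out.shape[1] == 3
        assert est.n_segments_ == len(est.segments_)
        clone_params = est.set_params(min_len=2.0).get_params()
        assert clone_params["min_len"] == 2.0


class TestDPOracle:
    def brute_force(self, tr, params, max_segments):
        """Enumerate all partitions into <= max_segments admissible pieces."""
        n = len(tr.time)
        nmin = max(3, int(np.ceil(params.min_len / tr.dt)) + 1)
        best = (np.inf, None)
        for k in range(1, max_segments + 1):
            for cuts in itertools.combinations(range(nmin, n - nmin + 1), k - 1):
                bounds = [0, *cuts, n]
                if any(b - a < nmin for a, b in zip(bounds[:-1], bounds[1:])):
                    continue
                tot = 0.0
                for a, b in zip(bounds[:-1], bounds[1:]):
                    _, _, resid, _ = _ols(tr.time[a:b], tr.extension[a:b])
                    tot += sm.segment_score(resid)
                if tot < best[0]:
                    best = (tot, bounds)
        return best

    def test_dp_matches_enumeration(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 12, 0.2)  # 60 samples
        y = np.where(t < 6, 10.0, 10.0 + 1.5 * (t - 6)) + rng.normal(0, 1.0, len(t))
        tr = sm.Trace(t, y, np.full_like(t, 25.0))
        p = sm.SegmentationParams(settle=0, overlap=0)
        dp = sm.dp_segment(tr, p, max_segments=3)
        brute_tot, _ = self.brute_force(tr, p, 3)
        assert sum(s.score for s in dp.segments) == pytest.approx(brute_tot, abs=1e-9)

    def test_noiseless_k_piece_exact_knots(self, piecewise_trace_factory):
        tr, knots = piecewise_trace_factory([8.0, 6.0, 8.0], [0.0, 3.0, 0.5])
        dp = sm.dp_segment(tr, sm.SegmentationParams(settle=0), max_segments=6)
        ends = [s.t_end for s in dp.segments[:-1]]
        assert len(ends) == len(knots)
        for e, k in zip(ends, knots):
            assert abs(e - k) <= tr.dt + 1e-9

    @pytest.mark.parametrize("seed", range(3))
    def test_greedy_never_beats_dp(self, seed, piecewise_trace_factory):
        tr, _ = piecewise_trace_factory([15.0, 15.0], [0.0, 1.0], sigma=6.0, seed=seed)
        p = sm.SegmentationParams(settle=0, overlap=0)
        greedy = sm.segment_trace(tr, p)
        dp = sm.dp_segment(tr, p, max_segments=max(4, len(greedy.segments)))
        assert sum(s.score for s in greedy.segments) >= sum(s.score for s in dp.segments) - 1e-9

    def test_too_long_input_rejected(self):
        t = np.arange(0, 500, 0.2)
        tr = sm.Trace(t, np.zeros_like(t), np.full_like(t, 25.0))
        with pytest.raises(ValueError):
            sm.dp_segment(tr, max_samples=1000)
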