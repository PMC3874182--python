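"""Extension summaries, pause ladders and extension-per-nt estimation."""

import numpy as np
import pytest

import smtrace as sm
from smtrace.binding import (
    PauseLevel,
    RECA_EXT_PER_NT,
    pause_histogram,
    pooled_ext_per_nt,
)
from smtrace.segmentation import GreedySegmenter


def simulate_and_segment(seed, length_nt=700, sigma=10.0, force=56.0, **kin):
    trace, gt = sm.simulate_binding_trace(
        sm.standard_binding_protocol(force),
        sm.FilamentSpec(length_nt),
        sm.BindingKinetics(**kin),
        sm.NoiseModel(sigma=sigma),
        seed=seed,
    )
    return trace, GreedySegmenter().fit(trace).result_, gt


class TestDeltaExtension:
    def test_noiseless_control_gives_zero(self):
        trace = sm.simulate_control_trace(
            sm.standard_binding_protocol(56.0), sm.NoiseModel(sigma=0.0), seed=0
        )
        summ = sm.delta_extension(trace)
        assert summ.delta_L == pytest.approx(0.0, abs=1e-9)
        assert summ.force == pytest.approx(56.0)

    def test_one_bound_filament_gives_84nm(self):
        trace, _, _ = simulate_and_segment(
            0, sigma=0.0, forced_nucleation_times=(125.0,), nucleation_rate=0.0
        )
        summ = sm.delta_extension(trace)
        assert summ.delta_L == pytest.approx(84.0, abs=1e-9)

    def test_window_outside_phase_rejected(self):
        trace = sm.simulate_control_trace(
            sm.standard_binding_protocol(56.0), sm.NoiseModel(sigma=0.0), seed=0
        )
        with pytest.raises(ValueError):
            sm.delta_extension(trace, window=(110.0, 130.0))

    def test_elastic_correction_matters(self):
        """Raw 56-40 pN difference would inflate dL by ~79 nm on lambda DNA."""
        trace = sm.simulate_control_trace(
            sm.standard_binding_protocol(56.0), sm.NoiseModel(sigma=0.0), seed=0
        )
        base_raw = sm.baseline_extension(trace, elastic_correction=False)
        base = sm.baseline_extension(trace)
        expected = 48502 * 0.34 * 3e-4 * 16  # L0 * compliance * dF
        assert base - base_raw == pytest.approx(expected, rel=1e-3)


class TestDetectPauses:
    def test_single_plateau_detected_at_84(self):
        trace, seg, _ = simulate_and_segment(
            0, sigma=0.0, forced_nucleation_times=(125.0,), nucleation_rate=0.0
        )
        pauses = sm.detect_pauses(seg, trace)
        levels = sorted(p.level for p in pauses if p.level > 20)
        assert len(levels) == 1
        assert levels[0] == pytest.approx(84.0, abs=0.1)

    def test_ramp_only_trace_has_no_positive_pause(self):
        # growth fills the whole high-force window: no plateau above baseline
        trace, gt = sm.simulate_binding_trace(
            sm.standard_binding_protocol(56.0),
            sm.FilamentSpec(2000),
            sm.BindingKinetics(forced_nucleation_times=(125.0,), nucleation_rate=0.0, growth_speed=1.0),
            sm.NoiseModel(sigma=0.0),
            seed=0,
        )
        seg = GreedySegmenter().fit(trace).result_
        pauses = sm.detect_pauses(seg, trace)
        assert [p for p in pauses if p.level > 20] == []

    def test_two_sequential_filaments_give_both_levels(self):
        trace, seg, _ = simulate_and_segment(
            0,
            sigma=0.0,
            forced_nucleation_times=(125.0, 185.0),
            nucleation_rate=0.0,
        )
        pauses = sorted(
            (p.level for p in sm.detect_pauses(seg, trace) if p.level > 20)
        )
        assert pauses == pytest.approx([84.0, 168.0], abs=0.1)

    def test_empty_segmentation_rejected(self):
        from smtrace.segmentation import SegmentationResult

        with pytest.raises(ValueError):
            sm.detect_pauses(SegmentationResult())


class TestPauseHistogram:
    def test_single_level_cohort_single_peak(self):
        pauses = [PauseLevel(84.0 + d, 5.0, 0.0) for d in (-1, 0, 1)]
        hist = pause_histogram(pauses)
        assert len(hist.peak_levels) == 1
        assert hist.peak_levels[0] == pytest.approx(84.0, abs=1.0)

    def test_three_level_seeded_cohort(self):
        rng = np.random.default_rng(5)
        pauses = [
            PauseLevel(level + rng.normal(0, 5), rng.uniform(3, 10), 0.0)
            for level in (84.0, 168.0, 252.0)
            for _ in range(20)
        ]
        hist = pause_histogram(pauses, bin_width=10.0)
        assert len(hist.peak_levels) == 3
        for peak, truth in zip(hist.peak_levels, (84, 168, 252)):
            assert abs(peak - truth) <= 10.0

    def test_oversized_bins_merge_peaks(self):
        rng = np.random.default_rng(6)
        pauses = [
            PauseLevel(level + rng.normal(0, 5), 5.0, 0.0)
            for level in (84.0, 168.0)
            for _ in range(20)
        ]
        hist = pause_histogram(pauses, bin_width=120.0)
        assert len(hist.peak_levels) < 2 or np.ptp(hist.peak_levels) < 120


class TestExtPerNt:
    def test_single_peak_arithmetic(self):
        est = sm.ext_per_nt([84.0], 700)
        assert est.value == pytest.approx(0.12)
        assert est.n_pauses == 1

    def test_consistent_multiples_have_zero_spread(self):
        est = sm.ext_per_nt([84.0, 168.0], 700)
        assert est.value == pytest.approx(0.12)
        assert est.sd == pytest.approx(0.0, abs=1e-12)

    def test_missing_first_multiple_still_resolved(self):
        est = sm.ext_per_nt([96.0, 144.0], 400)
        assert est.value == pytest.approx(0.12, abs=1e-6)

    def test_no_peaks_rejected(self):
        with pytest.raises(ValueError):
            sm.ext_per_nt([], 700)

    @pytest.mark.parametrize("g", [0.08, 0.12, 0.17])
    def test_parameter_recovery_across_generating_values(self, g):
        """Pipeline recovers the generating extension/nt from noisy cohorts."""
        pairs = []
        for i in range(8):
            trace, _ = sm.simulate_binding_trace(
                sm.standard_binding_protocol(56.0),
                sm.FilamentSpec(700, ext_per_nt=g),
                sm.BindingKinetics(),
                sm.NoiseModel(),
                seed=300 + i,
            )
            pairs.append((trace, GreedySegmenter().fit(trace).result_))
        est = sm.ExtensionPerNtEstimator(filament_nt=700).fit(pairs)
        assert est.value_ == pytest.approx(g, abs=max(2 * est.sd_, 0.01))

    def test_pooled_estimate_weights_by_pause_count(self):
        from smtrace.binding import ExtPerNtEstimate

        pooled = pooled_ext_per_nt(
            [ExtPerNtEstimate(0.12, 0.01, 3), ExtPerNtEstimate(0.13, 0.01, 1)]
        )
        assert pooled.value == pytest.approx((0.12 * 3 + 0.13) / 4)
        assert pooled.n_pauses == 4


class TestCoverage:
    def test_full_coverage(self):
        assert sm.coverage_fraction(0.17).fraction == pytest.approx(1.0)

    def test_rad51_value_implies_70_percent(self):
        frac = sm.coverage_fraction(0.12, RECA_EXT_PER_NT).fraction
        assert frac == pytest.approx(0.706, abs=0.001)

    def test_half_coverage(self):
        assert sm.coverage_fraction(0.085, 0.17).fraction == pytest.approx(0.5)

    def test_scale_consistency(self):
        a = sm.coverage_fraction(0.12, 0.17).fraction
        b = sm.coverage_fraction(0.24, 0.34).fraction
        assert a == pytest.approx(b)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sm.coverage_fraction(0.0, 0.17)
        with pytest.raises(ValueError):
            sm.coverage_fraction(0.12, 0.0)


class TestCohortSummary:
    def make_summaries(self):
        out = []
        for mode, dls in [("3p5p", [100, 120, 140]), ("3p3p", [1, -2, 3])]:
            for dl in dls:
                out.append(sm.ExtensionSummary(dl, (225.0, 240.0), 56.0, mode))
        out.append(sm.ExtensionSummary(5.0, (225.0, 240.0), 58.0, "5p5p"))
        return out

    def test_group_counts_conserved(self):
        table = sm.cohort_summary(self.make_summaries())
        assert table["n"].sum() == 7

    def test_single_member_group_flagged(self):
        table = sm.cohort_summary(self.make_summaries())
        row = table[table["mode"] == "5p5p"].iloc[0]
        assert row["single"]
        assert row["sd_dL"] == 0.0

    def test_force_binning(self):
        table = sm.cohort_summary(self.make_summaries(), force_bins=[(56.0, 58.0)])
        assert set(table["force_bin"]) == {"56-58"}
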