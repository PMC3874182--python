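"""Turn-key replication studies on synthetic cohorts.

Each function simulates a cohort under the standard study conditions
(5 Hz sampling, 10 nm noise, the 40 pN / test-force / 40 pN protocol),
runs the full analysis pipeline on it, and returns the recovered
quantities. They are the package's self-validation drivers: parameter
recovery under realistic conditions, plus the analytic identities of
the mechanics model.
"""

from __future__ import annotations

import numpy as np

from . import binding as binding_mod
from . import exchange as exchange_mod
from .calibration import OverstretchCalibrator
from .mechanics import MechanicsParams, force_extension
from .segmentation import GreedySegmenter, SegmentationParams, dp_segment, segment_trace
from .simulate import (
    BindingKinetics,
    FilamentSpec,
    NoiseModel,
    Trace,
    simulate_binding_trace,
    simulate_control_trace,
    simulate_exchange_trace,
    simulate_overstretch_ramp,
    standard_binding_protocol,
)

__all__ = [
    "ext_per_nt_recovery_study",
    "exchange_rate_recovery_study",
    "calibration_study",
    "overstretch_ratio",
    "segmentation_oracle_study",
    "mode_selectivity_study",
]

STUDY_LENGTHS = (400, 700, 1000, 1600)  # nt


def _spawn(seed, *key) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=seed.entropy, spawn_key=(*seed.spawn_key, *key))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=key)


def ext_per_nt_recovery_study(
    seed: int = 42,
    n_per_length: int = 15,
    lengths: tuple[int, ...] = STUDY_LENGTHS,
    force: float = 56.0,
    nucleation_rate: float = 0.02,
) -> dict:
    """Recover the extension/nt from pause ladders of a binding cohort.

    Simulates ``n_per_length`` traces per filament length at the
    standard conditions, segments each, pools pause levels per length,
    and estimates the extension per nucleotide per length and pooled.

    Pause points are resolvable only when binding is rare — dwell times
    at a completed filament must exceed several seconds — so this study
    runs in the rare-nucleation regime (0.02 events/s, mean wait 50 s)
    rather than the abundant-binding regime of the selectivity study.
    """
    segmenter = GreedySegmenter()
    per_length: dict[int, binding_mod.ExtPerNtEstimate] = {}
    for li, length in enumerate(lengths):
        pairs = []
        for ri in range(n_per_length):
            child = _spawn(seed, li, ri)
            trace, _ = simulate_binding_trace(
                standard_binding_protocol(force),
                FilamentSpec(length),
                BindingKinetics(nucleation_rate=nucleation_rate),
                NoiseModel(),
                seed=child,
            )
            pairs.append((trace, segmenter.fit(trace).result_))
        est = binding_mod.ExtensionPerNtEstimator(filament_nt=length).fit(pairs)
        per_length[length] = est.estimate_
    pooled = binding_mod.pooled_ext_per_nt(list(per_length.values()))
    return {
        "per_length": per_length,
        "pooled": pooled,
        "coverage": binding_mod.coverage_fraction(pooled.value),
        "n_traces": n_per_length * len(lengths),
    }


def exchange_rate_recovery_study(
    seed: int = 7,
    rate: float = 0.21,
    n_traces: int = 40,
    n_boot: int = 1000,
) -> exchange_mod.RateEstimate:
    """Recover a strand-exchange rate from a simulated cohort."""
    segmenter = GreedySegmenter()
    results = []
    for i in range(n_traces):
        trace, _ = simulate_exchange_trace(rate, seed=_spawn(seed, 0, i))
        results.append(segmenter.fit(trace).result_)
    slopes = exchange_mod.trace_slopes(results)
    return exchange_mod.characteristic_rate(slopes, n_boot=n_boot, seed=_spawn(seed, 1))


def calibration_study(bead_scale: float = 1.0, sigma: float = 0.0, seed: int = 0) -> dict:
    """Detect the overstretching transition on a synthetic calibration ramp."""
    ramp = simulate_overstretch_ramp(
        bead_scale=bead_scale, noise=NoiseModel(sigma=sigma), seed=_spawn(seed, 0)
    )
    cal = OverstretchCalibrator().fit(ramp)
    return {
        "transition_force_nominal": cal.transition_force_,
        "width": cal.width_,
        "bead_scale": cal.scale_,
    }


def overstretch_ratio(force: float = 70.0, n_bp: int = 48502) -> float:
    """Model extension above the transition relative to B-form contour."""
    params = MechanicsParams(low_force_compliance=0.0)
    return force_extension(force, n_bp, params) / (n_bp * params.bform_rise)


def _random_piecewise_trace(rng: np.random.Generator, sigma: float) -> tuple[Trace, list[float]]:
    """2–4 pieces of >= 3 s each with well-separated slopes."""
    n_pieces = int(rng.integers(2, 5))
    durations = rng.uniform(4.0, 8.0, n_pieces)
    slopes = rng.choice([-2.0, 0.0, 1.0, 2.0, 3.0], n_pieces, replace=False)
    dt = 0.2
    t = np.arange(0.0, durations.sum(), dt)
    y = np.empty_like(t)
    t0, y0 = 0.0, 100.0
    knots = []
    for dur, sl in zip(durations, slopes):
        selm = (t >= t0 - 1e-9) & (t < t0 + dur - 1e-9)
        y[selm] = y0 + sl * (t[selm] - t0)
        y0 += sl * dur
        t0 += dur
        knots.append(t0)
    if sigma > 0:
        y = y + rng.normal(0, sigma, len(t))
    return Trace(t, y, np.full_like(t, 25.0)), knots[:-1]


def segmentation_oracle_study(seed: int = 0, n_traces: int = 50, sigma_noisy: float = 4.0) -> dict:
    """Greedy-vs-exact-DP comparison on seeded piecewise-linear traces.

    On noiseless traces both methods must recover every knot within one
    sample; on noisy traces the DP total score is a lower bound on the
    greedy total (it is the optimum over all partitions).
    """
    params = SegmentationParams(settle=0.0, overlap=0.0)
    rng = np.random.default_rng(_spawn(seed, 0))
    knot_errors: list[float] = []
    n_knots = 0
    for _ in range(n_traces):
        tr, knots = _random_piecewise_trace(rng, sigma=0.0)
        greedy = segment_trace(tr, params)
        dp = dp_segment(tr, params, max_segments=6)
        for res in (greedy, dp):
            ends = [s.t_end for s in res.segments[:-1]]
            assert len(ends) == len(knots), "wrong number of recovered pieces"
            knot_errors.extend(abs(e - k) for e, k in zip(ends, knots))
        n_knots += len(knots)
    max_knot_error = max(knot_errors) if knot_errors else 0.0

    margins: list[float] = []
    for _ in range(n_traces):
        tr, _ = _random_piecewise_trace(rng, sigma=sigma_noisy)
        greedy = segment_trace(tr, params)
        dp = dp_segment(tr, params, max_segments=max(6, len(greedy.segments)))
        margins.append(
            sum(s.score for s in greedy.segments) - sum(s.score for s in dp.segments)
        )
    return {
        "max_knot_error_s": max_knot_error,
        "n_knots": n_knots,
        "min_greedy_minus_dp": min(margins),
        "dt": 0.2,
    }


def mode_selectivity_study(
    seed: int = 0,
    n_per_group: int = 8,
    forces: tuple[float, ...] = (56.0, 58.0),
) -> dict:
    """Pulling-geometry selectivity of filament binding at 56–58 pN.

    Simulates the three pulling geometries plus filament-free controls,
    measures dL over the 105–120 s window, and reports group means/sds
    and how many pooled standard deviations each geometry sits above
    the controls. Also verifies force-release unbinding: the terminal
    40 pN phase returns the extension gain to zero.
    """
    segmenter = GreedySegmenter()
    groups: dict[str, list[float]] = {m: [] for m in ("3p5p", "3p3p", "5p5p", "control")}
    terminal_gains: list[float] = []
    for gi, mode in enumerate(("3p5p", "3p3p", "5p5p")):
        for ri in range(n_per_group):
            force = forces[ri % len(forces)]
            child = _spawn(seed, gi, ri)
            trace, _ = simulate_binding_trace(
                standard_binding_protocol(force),
                FilamentSpec(700),
                BindingKinetics(mode=mode),
                NoiseModel(),
                seed=child,
            )
            segmenter.fit(trace)
            groups[mode].append(binding_mod.delta_extension(trace).delta_L)
            if mode == "3p5p":
                # terminal gain after the force release, vs the naked baseline
                base = force_extension(40.0, trace.construct_bp)
                terminal_gains.append(float(np.mean(trace.extension[-25:]) - base))
    for ri in range(n_per_group):
        force = forces[ri % len(forces)]
        trace = simulate_control_trace(
            standard_binding_protocol(force), NoiseModel(), seed=_spawn(seed, 3, ri)
        )
        groups["control"].append(binding_mod.delta_extension(trace).delta_L)

    stats = {
        m: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)), "n": len(v)}
        for m, v in groups.items()
    }
    ctrl = stats["control"]
    separations = {}
    for m in ("3p5p", "3p3p", "5p5p"):
        pooled_sd = float(np.sqrt(0.5 * (stats[m]["sd"] ** 2 + ctrl["sd"] ** 2)))
        separations[m] = (stats[m]["mean"] - ctrl["mean"]) / pooled_sd
    return {
        "stats": stats,
        "separations": separations,
        "mean_terminal_gain": float(np.mean(terminal_gains)),
        "sd_terminal_gain": float(np.std(terminal_gains, ddof=1)),
    }
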