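"""Binding-experiment observables from segmented extension traces.

Turns segmentations of constant-force binding traces into the
quantities of interest: the filament-induced extension gain dL over a
late measurement window (105–120 s after the force step by default),
pause levels and their duration-weighted histogram, the characteristic
extension per filament nucleotide, and the filament coverage implied by
comparing that value against a fully-coated reference (0.17 nm/nt, the
RecA value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .mechanics import MechanicsParams, force_extension
from .segmentation import SegmentationResult
from .simulate import Trace

__all__ = [
    "ExtensionSummary",
    "PauseLevel",
    "PauseHistogram",
    "ExtPerNtEstimate",
    "CoverageEstimate",
    "baseline_extension",
    "delta_extension",
    "detect_pauses",
    "pause_histogram",
    "ext_per_nt",
    "pooled_ext_per_nt",
    "coverage_fraction",
    "cohort_summary",
    "ExtensionPerNtEstimator",
]

MEASUREMENT_WINDOW = (105.0, 120.0)  # s after the force step
RECA_EXT_PER_NT = 0.17  # nm/nt, fully coated reference filament
EXT_PER_NT_RANGE = (0.05, 0.20)  # physically admissible nm/nt for comb fitting


@dataclass
class ExtensionSummary:
    delta_L: float  # nm beyond the naked-DNA baseline
    window: tuple[float, float]  # s, absolute trace time
    force: float  # pN during the window
    mode: str = ""


@dataclass
class PauseLevel:
    level: float  # nm above baseline
    duration: float  # s
    slope: float  # nm/s


@dataclass
class PauseHistogram:
    bin_edges: np.ndarray
    weights: np.ndarray  # duration-weighted mass per bin
    peak_levels: np.ndarray  # refined peak centers, nm
    peak_weights: np.ndarray


@dataclass
class ExtPerNtEstimate:
    value: float  # nm/nt
    sd: float
    n_pauses: int


@dataclass
class CoverageEstimate:
    fraction: float
    reference_ext: float = RECA_EXT_PER_NT


# ---------------------------------------------------------------------------


def _high_force_phase(trace: Trace) -> tuple[int, int, float]:
    phases = trace.phases()
    return max(phases, key=lambda p: p[2])


def baseline_extension(
    trace: Trace,
    mechanics: MechanicsParams | None = None,
    pre_window: float = 20.0,
    elastic_correction: bool = True,
) -> float:
    """Naked-DNA baseline (nm) at the trace's high-force phase.

    Estimated from the molecule itself: the mean extension over the
    last ``pre_window`` seconds of the phase preceding the high-force
    step, plus the model-predicted elastic lengthening of naked dsDNA
    between the two forces (switchable off for a raw difference).
    """
    mechanics = mechanics or MechanicsParams()
    phases = trace.phases()
    hi = max(phases, key=lambda p: p[2])
    idx = phases.index(hi)
    if idx == 0:
        raise ValueError("no pre-step phase before the high-force phase")
    a, b, f_pre = phases[idx - 1]
    t = trace.time
    t_end = t[b - 1]
    sel = slice(max(a, b - int(round(pre_window / trace.dt))), b)
    base = float(np.mean(trace.extension[sel]))
    if elastic_correction:
        base += force_extension(hi[2], trace.construct_bp, mechanics) - force_extension(
            f_pre, trace.construct_bp, mechanics
        )
    return base


def delta_extension(
    trace: Trace,
    segmentation: SegmentationResult | None = None,
    baseline: float | None = None,
    window: tuple[float, float] = MEASUREMENT_WINDOW,
    mechanics: MechanicsParams | None = None,
) -> ExtensionSummary:
    """Filament-induced extension gain averaged over ``window``.

    ``window`` is measured from the start of the high-force phase and
    must lie inside it. ``baseline`` defaults to
    :func:`baseline_extension`.
    """
    a, b, f_hi = _high_force_phase(trace)
    t = trace.time
    t0 = t[a] + window[0]
    t1 = t[a] + window[1]
    if t1 <= t0:
        raise ValueError("window must have positive length")
    if t0 < t[a] - 1e-9 or t1 > t[b - 1] + trace.dt + 1e-9:
        raise ValueError("measurement window extends outside the high-force phase")
    if baseline is None:
        baseline = baseline_extension(trace, mechanics)
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    sel[b:] = False  # never reach into the following phase
    dL = float(np.mean(trace.extension[sel]) - baseline)
    return ExtensionSummary(dL, (float(t0), float(t1)), f_hi, str(trace.meta.get("mode", "")))


def detect_pauses(
    segmentation: SegmentationResult,
    trace: Trace | None = None,
    baseline: float | None = None,
    slope_threshold: float | None = None,
    window: tuple[float, float] | None = None,
    mechanics: MechanicsParams | None = None,
    slope_cap: float = 0.5,
) -> list[PauseLevel]:
    """Plateau segments of a segmentation, as levels above baseline.

    A segment is a pause when |slope| <= max(0.02 nm/s,
    min(2 * slope_se, ``slope_cap``)), or <= ``slope_threshold`` when
    given. The absolute cap matters for short segments, whose slope
    standard error is so large that "consistent with zero slope" would
    admit clearly growing stretches. By default only segments inside
    the high-force phase are considered; pass ``window`` (s) to
    override. Levels are the segment-mean extension minus ``baseline``
    (default: :func:`baseline_extension` of the trace).
    """
    if not segmentation.segments:
        raise ValueError("empty segmentation")
    if trace is not None:
        if baseline is None:
            baseline = baseline_extension(trace, mechanics)
        if window is None:
            a, b, _ = _high_force_phase(trace)
            window = (float(trace.time[a]), float(trace.time[b - 1]))
    if baseline is None:
        baseline = 0.0
    pauses = []
    for seg in segmentation.segments:
        if window is not None and not (
            seg.t_start >= window[0] - 1e-9 and seg.t_end <= window[1] + 1e-9
        ):
            continue
        if slope_threshold is not None:
            thr = slope_threshold
        else:
            se = seg.slope_se if np.isfinite(seg.slope_se) else 0.0
            thr = max(0.02, min(2.0 * se, slope_cap))
        if abs(seg.slope) <= thr:
            t_mid = 0.5 * (seg.t_start + seg.t_end)
            level = seg.intercept + seg.slope * t_mid - baseline
            pauses.append(PauseLevel(float(level), seg.duration, seg.slope))
    return pauses


def pause_histogram(
    pauses: list[PauseLevel],
    bin_width: float = 10.0,
    prominence_frac: float = 0.2,
) -> PauseHistogram:
    """Duration-weighted histogram of pause levels with peak locations.

    Peaks are local maxima whose prominence exceeds ``prominence_frac``
    of the tallest bin; each peak center is refined as the
    duration-weighted mean of the levels within one bin width of it.
    """
    if not pauses:
        raise ValueError("need at least one pause")
    levels = np.array([p.level for p in pauses])
    weights = np.array([p.duration for p in pauses])
    lo = np.floor(levels.min() / bin_width) * bin_width - bin_width
    hi = np.ceil(levels.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist, edges = np.histogram(levels, bins=edges, weights=weights)
    padded = np.concatenate([[0.0], hist, [0.0]])
    idx, _ = find_peaks(padded, prominence=prominence_frac * hist.max())
    idx = idx - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_levels, peak_weights = [], []
    for i in idx:
        near = np.abs(levels - centers[i]) <= bin_width
        if near.any():
            w = weights[near]
            peak_levels.append(float(np.average(levels[near], weights=w)))
            peak_weights.append(float(w.sum()))
    order = np.argsort(peak_levels)
    return PauseHistogram(
        edges, hist, np.array(peak_levels)[order], np.array(peak_weights)[order]
    )


def _assign_multiples(
    peak_levels: np.ndarray,
    peak_weights: np.ndarray,
    unit_range: tuple[float, float],
    max_mismatch: float = 0.25,
):
    """Comb fit: find the unit spacing and integer multiple of each peak.

    Scans candidate units over ``unit_range``; the cost is the weighted
    squared fractional distance of each peak to its nearest integer
    multiple. Among near-tied costs the largest unit wins, which rejects
    subharmonic combs (a unit of u/2 always fits at least as well as u).
    Peaks off their multiple by more than ``max_mismatch`` are dropped.
    """
    lo, hi = unit_range
    grid = np.linspace(lo, hi, 601)
    k = np.maximum(1, np.round(peak_levels[None, :] / grid[:, None]))
    frac = peak_levels[None, :] / (k * grid[:, None]) - 1.0
    cost = np.sum(peak_weights[None, :] * frac**2, axis=1)
    tol = 1e-3 * np.sum(peak_weights)
    candidates = np.flatnonzero(cost <= cost.min() + tol)
    u = grid[candidates[-1]]
    ks = np.maximum(1, np.round(peak_levels / u)).astype(int)
    keep = np.abs(peak_levels / (ks * u) - 1.0) <= max_mismatch
    return ks, keep


def ext_per_nt(
    peak_levels,
    filament_nt: int,
    peak_weights=None,
    unit_range_nm_per_nt: tuple[float, float] = EXT_PER_NT_RANGE,
) -> ExtPerNtEstimate:
    """Extension per filament nucleotide from pause-histogram peaks.

    Each peak is assigned to an integer multiple k of the filament
    length; the estimate is the weight-averaged ``level_k / (k * nt)``
    with the spread of the per-peak values as its sd.
    """
    levels = np.atleast_1d(np.asarray(peak_levels, dtype=float))
    if filament_nt <= 0:
        raise ValueError("filament_nt must be positive")
    if len(levels) == 0:
        raise ValueError("no peaks to assign")
    w = (
        np.ones_like(levels)
        if peak_weights is None
        else np.atleast_1d(np.asarray(peak_weights, dtype=float))
    )
    unit_range = (
        unit_range_nm_per_nt[0] * filament_nt,
        unit_range_nm_per_nt[1] * filament_nt,
    )
    ks, keep = _assign_multiples(levels, w, unit_range)
    if not keep.any():
        raise ValueError("no peaks assignable to integer filament multiples")
    vals = levels[keep] / (ks[keep] * filament_nt)
    ww = w[keep]
    value = float(np.average(vals, weights=ww))
    if len(vals) > 1:
        sd = float(np.sqrt(np.average((vals - value) ** 2, weights=ww)))
    else:
        sd = 0.0
    return ExtPerNtEstimate(value, sd, int(keep.sum()))


def pooled_ext_per_nt(estimates: list[ExtPerNtEstimate]) -> ExtPerNtEstimate:
    """Pool per-filament-length estimates, weighting by pause count."""
    ests = [e for e in estimates if e.n_pauses > 0]
    if not ests:
        raise ValueError("no estimates to pool")
    w = np.array([e.n_pauses for e in ests], dtype=float)
    v = np.array([e.value for e in ests])
    value = float(np.average(v, weights=w))
    sd = float(np.sqrt(np.average((v - value) ** 2, weights=w))) if len(v) > 1 else ests[0].sd
    return ExtPerNtEstimate(value, sd, int(w.sum()))


def coverage_fraction(
    est: ExtPerNtEstimate | float, reference_ext: float = RECA_EXT_PER_NT
) -> CoverageEstimate:
    """Filament coverage implied by the measured extension per nt.

    fraction = value / reference, clipped to 1 — the coverage a fully
    stretching but incompletely coated filament would need to produce
    the observed extension.
    """
    value = est.value if isinstance(est, ExtPerNtEstimate) else float(est)
    if value <= 0 or reference_ext <= 0:
        raise ValueError("extension values must be positive")
    return CoverageEstimate(min(1.0, value / reference_ext), reference_ext)


def cohort_summary(
    summaries: list[ExtensionSummary],
    force_bins: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Mean ± sd dL by pulling mode and force bin.

    Rows: (mode, force_bin) with columns mean_dL, sd_dL (0 with
    ``single`` flag when n = 1), n.
    """
    if not summaries:
        raise ValueError("no summaries")
    rows = []
    for s in summaries:
        fb = None
        if force_bins is not None:
            for lo, hi in force_bins:
                if lo <= s.force <= hi:
                    fb = f"{lo:g}-{hi:g}"
                    break
            if fb is None:
                warnings.warn(f"summary at {s.force} pN falls in no force bin; dropped")
                continue
        else:
            fb = f"{s.force:g}"
        rows.append({"mode": s.mode or "control", "force_bin": fb, "delta_L": s.delta_L})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["mode", "force_bin"])["delta_L"]
        .agg(mean_dL="mean", sd_dL=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0, n="count")
        .reset_index()
    )
    out["single"] = out["n"] == 1
    return out


# ---------------------------------------------------------------------------


class ExtensionPerNtEstimator(BaseEstimator):
    """End-to-end pause-ladder estimator of the extension per nucleotide.

    ``fit`` takes a list of (trace, segmentation) pairs from binding
    experiments that all used filaments of ``filament_nt`` nucleotides,
    pools the detected pause levels into a duration-weighted histogram,
    and estimates the characteristic extension per nt from the peak
    ladder. Fitted attributes: ``value_``, ``sd_``, ``n_pauses_``,
    ``histogram_``.

    ``min_duration`` discards plateaus dwelling less than a few times
    the minimum fit length: genuine pause points last many seconds
    (binding must be rare for them to exist at all), while brief flat
    stretches inside a growth phase are noise artifacts whose levels
    sit at no particular multiple and can derail the ladder fit.
    """

    def __init__(
        self,
        filament_nt: int = 700,
        bin_width: float = 10.0,
        slope_threshold: float | None = None,
        min_level: float = 20.0,
        min_duration: float = 5.0,
    ):
        self.filament_nt = filament_nt
        self.bin_width = bin_width
        self.slope_threshold = slope_threshold
        self.min_level = min_level
        self.min_duration = min_duration

    def fit(self, pairs, y=None) -> "ExtensionPerNtEstimator":
        pauses: list[PauseLevel] = []
        for trace, segmentation in pairs:
            try:
                found = detect_pauses(
                    segmentation, trace, slope_threshold=self.slope_threshold
                )
            except ValueError:
                continue
            pauses.extend(
                p
                for p in found
                if p.level >= self.min_level and p.duration >= self.min_duration
            )
        if not pauses:
            raise ValueError("no pause levels found in the cohort")
        self.histogram_ = pause_histogram(pauses, bin_width=self.bin_width)
        est = ext_per_nt(
            self.histogram_.peak_levels, self.filament_nt, self.histogram_.peak_weights
        )
        self.value_ = est.value
        self.sd_ = est.sd
        self.n_pauses_ = len(pauses)
        self.estimate_ = est
        return self
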