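"""Greedy piecewise-linear segmentation of extension-vs-time traces.

The segmenter identifies intervals of constant extension growth. From a
starting point it fits ordinary least squares lines to every candidate
interval lasting at least ``min_len`` seconds, scores each fit by a
residual-structure statistic, keeps the best-scoring line, and restarts
from its endpoint (minus a small overlap) until the analysis window is
exhausted. Analysis windows begin ``settle`` seconds after each force
change, and short high-noise bursts (< ``skip_max`` s) at growth-rate
transitions may be skipped and logged.

The score multiplies the mean absolute residual by the mean absolute
residual autocorrelation over all positive lags. On featureless data
the autocorrelation term decays like n^-1/2, so long homogeneous fits
win; residual structure from crossing a growth-rate change inflates
both factors sharply. (A "literal" variant using the signed residual
sum and the unnormalized autocorrelation sum is retained for
comparison; for intercept-OLS residuals the signed sum is identically
zero and the biased autocorrelations sum to exactly -1/2, which makes
that variant degenerate — see the methods note.)

An exact dynamic-programming segmenter over full partitions is provided
as a test oracle only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .simulate import Trace

__all__ = [
    "SegmentationParams",
    "Segment",
    "SegmentationResult",
    "fit_line",
    "segment_score",
    "best_segment_from",
    "segment_trace",
    "dp_segment",
    "GreedySegmenter",
]

_SCORE_TIE_ATOL = 1e-10  # nm-scale scores below this are "exact fit" ties


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable constants of the greedy segmenter (seconds unless noted)."""

    min_len: float = 2.0  # minimum fitted interval
    skip_max: float = 1.0  # longest high-noise region that may be skipped
    overlap: float = 0.5  # successive intervals may share this much
    settle: float = 20.0  # dead time after each force change
    skip_zscore: float = 3.0  # robust z threshold flagging high noise
    score_mode: str = "robust"  # "robust" | "literal"

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")
        if not 0 <= self.overlap < self.min_len:
            raise ValueError("overlap must lie in [0, min_len)")
        if self.settle < 0 or self.skip_max < 0:
            raise ValueError("settle and skip_max must be non-negative")
        if self.score_mode not in ("robust", "literal"):
            raise ValueError("score_mode must be 'robust' or 'literal'")


@dataclass
class Segment:
    """A fitted constant-growth interval."""

    t_start: float
    t_end: float
    slope: float  # nm/s
    intercept: float  # nm at t=0
    score: float
    n_samples: int
    slope_se: float  # nm/s

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def to_dict(self) -> dict:
        return {
            "t_start": self.t_start,
            "t_end": self.t_end,
            "slope_nm_per_s": self.slope,
            "intercept_nm": self.intercept,
            "score": self.score,
            "n_samples": self.n_samples,
            "slope_se": self.slope_se,
        }


@dataclass
class SegmentationResult:
    segments: list[Segment] = field(default_factory=list)
    skipped: list[tuple[float, float]] = field(default_factory=list)
    analyzed_windows: list[tuple[float, float]] = field(default_factory=list)

    @property
    def slopes(self) -> np.ndarray:
        return np.array([s.slope for s in self.segments])

    def to_dict(self) -> dict:
        return {
            "segments": [s.to_dict() for s in self.segments],
            "skipped": [list(map(float, s)) for s in self.skipped],
            "analyzed_windows": [list(map(float, w)) for w in self.analyzed_windows],
        }


# ---------------------------------------------------------------------------
# primitives


def _ols(t: np.ndarray, y: np.ndarray):
    # NaN samples (masked high-noise bursts) are excluded from the fit
    valid = np.isfinite(y)
    if not valid.all():
        t, y = t[valid], y[valid]
    n = len(t)
    if n < 2:
        raise ValueError("need at least two finite samples")
    tbar = t.mean()
    ybar = y.mean()
    stt = float(np.sum((t - tbar) ** 2))
    if stt == 0.0:
        raise ValueError("degenerate fit: all time values equal")
    slope = float(np.sum((t - tbar) * (y - ybar)) / stt)
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    if n > 2:
        sigma2 = float(np.sum(resid**2) / (n - 2))
        slope_se = float(np.sqrt(sigma2 / stt))
    else:
        slope_se = float("nan")
    return slope, float(intercept), resid, slope_se


def fit_line(trace: Trace, i: int, j: int):
    """OLS of extension on time over samples ``i..j`` inclusive.

    Returns ``(slope, intercept, residuals)`` in nm/s, nm, nm.
    """
    if j - i + 1 < 2:
        raise ValueError("need at least two samples")
    slope, intercept, resid, _ = _ols(trace.time[i : j + 1], trace.extension[i : j + 1])
    return slope, intercept, resid


def _abs_autocorr(e: np.ndarray) -> tuple[float, float]:
    """(sum_k |rho_k|, sum_k rho_k) over positive lags, biased estimator."""
    n = len(e)
    c0 = float(np.dot(e, e))
    if c0 == 0.0:
        return 0.0, 0.0
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    fe = np.fft.rfft(e, nfft)
    acov = np.fft.irfft(fe * np.conj(fe), nfft)[:n]  # biased * n
    rho = acov[1:] / c0
    return float(np.sum(np.abs(rho))), float(np.sum(rho))


def segment_score(residuals: np.ndarray, mode: str = "robust") -> float:
    """Residual-structure score of a candidate line fit.

    robust (default): mean|e| * mean_k|rho_k| with rho_k the biased
    sample autocorrelation at lag k = 1..n-1. Zero iff the fit is exact.
    literal: |sum(e)|/n * sum_k rho_k, the verbatim published recipe
    (degenerate for intercept fits; kept for comparison).
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if n < 3:
        raise ValueError("need at least 3 residuals for an autocorrelation score")
    abs_sum, signed_sum = _abs_autocorr(e)
    if mode == "robust":
        return float(np.mean(np.abs(e)) * abs_sum / (n - 1))
    if mode == "literal":
        return float(abs(np.sum(e)) / n * signed_sum)
    raise ValueError("mode must be 'robust' or 'literal'")


def _min_samples(params: SegmentationParams, dt: float) -> int:
    # a segment must span >= min_len seconds and allow the score (>= 3 pts)
    return max(3, int(np.ceil(params.min_len / dt)) + 1)


def _scan_best_end(
    t: np.ndarray,
    y: np.ndarray,
    start: int,
    stop: int,
    params: SegmentationParams,
) -> tuple[int, Segment]:
    """Score every admissible end in [start+min, stop] and return the best.

    Ties within an absolute tolerance (exact fits) go to the longest
    candidate.
    """
    dt = float(t[1] - t[0])
    nmin = _min_samples(params, dt)
    ends = np.arange(start + nmin - 1, stop + 1)
    if len(ends) == 0:
        raise ValueError("insufficient data for a minimum-length segment")
    best = None
    for j in ends:
        tt, yy = t[start : j + 1], y[start : j + 1]
        if np.isfinite(yy).sum() < 3:
            continue
        slope, intercept, resid, slope_se = _ols(tt, yy)
        sc = segment_score(resid, params.score_mode)
        cand = (sc, j, slope, intercept, slope_se, len(resid))
        if best is None or sc < best[0] - _SCORE_TIE_ATOL:
            best = cand
        elif sc <= best[0] + _SCORE_TIE_ATOL and j > best[1]:
            best = cand
    if best is None:
        raise ValueError("insufficient finite data for a minimum-length segment")
    sc, j, slope, intercept, slope_se, n = best
    seg = Segment(float(t[start]), float(t[j]), slope, intercept, sc, n, slope_se)
    return j, seg


def best_segment_from(trace: Trace, start: int, params: SegmentationParams | None = None) -> Segment:
    """Best-scoring constant-growth interval beginning at sample ``start``.

    Every endpoint giving a duration of at least ``min_len`` is
    evaluated; the minimum-score line wins, ties broken by duration.
    """
    params = params or SegmentationParams()
    _, seg = _scan_best_end(trace.time, trace.extension, start, len(trace.time) - 1, params)
    return seg


# ---------------------------------------------------------------------------
# greedy driver


def _detect_bursts(
    t: np.ndarray,
    y: np.ndarray,
    w0: int,
    w1: int,
    params: SegmentationParams,
) -> list[tuple[int, int]]:
    """Short high-noise runs inside window [w0, w1] as (start, stop) spans.

    Samples are flagged when they deviate from a running-median local
    trend by more than ``skip_zscore`` robust standard deviations; only
    runs shorter than ``skip_max`` seconds qualify — longer excursions
    are real growth-rate changes and must be fitted, not skipped. A run
    must also carry excess z-mass of at least ``skip_zscore`` above the
    threshold, so single borderline noise samples are not flagged.
    """
    from scipy.signal import medfilt

    dt = float(t[1] - t[0])
    max_run = int(np.floor(params.skip_max / dt))
    if max_run < 1:
        return []
    yy = y[w0 : w1 + 1]
    # noise scale from second differences: immune to piecewise-linear trend
    d2 = np.diff(yy, 2)
    sigma = 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)
    if sigma < 1e-9:
        return []  # noiseless data has no noise bursts to skip
    k = min(max(3, int(round(params.min_len / dt)) | 1), (len(yy) - 1) | 1)
    trend = medfilt(yy, kernel_size=k)
    resid = yy - trend
    z = np.abs(resid) / sigma
    flagged = z > params.skip_zscore
    bursts: list[tuple[int, int]] = []
    i = 0
    n = len(flagged)
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            excess = float(np.sum(z[i:j] - params.skip_zscore))
            if (j - i) <= max_run and excess >= params.skip_zscore:
                bursts.append((w0 + i, w0 + j))
            i = j
        else:
            i += 1
    return bursts


def _segment_window(
    t: np.ndarray,
    y: np.ndarray,
    w0: int,
    w1: int,
    params: SegmentationParams,
) -> tuple[list[Segment], list[tuple[float, float]]]:
    dt = float(t[1] - t[0])
    nmin = _min_samples(params, dt)
    overlap_n = int(round(params.overlap / dt))
    segments: list[Segment] = []
    skipped: list[tuple[float, float]] = []
    y = y.astype(float).copy()
    for i0, i1 in _detect_bursts(t, y, w0, w1, params):
        skipped.append((float(t[i0]), float(t[min(i1, w1)])))
        y[i0:i1] = np.nan  # masked: excluded from every fit
    start = w0
    while w1 - start + 1 >= nmin:
        j, seg = _scan_best_end(t, y, start, w1, params)
        segments.append(seg)
        if j >= w1:
            break
        start = max(j - overlap_n, start + 1)
    # merge a sub-min_len tail into the final segment so the window is covered
    if segments:
        last = segments[-1]
        last_j = int(round((last.t_end - t[0]) / dt))
        if last_j < w1 and (w1 - last_j) < nmin - 1:
            start_i = int(round((last.t_start - t[0]) / dt))
            slope, intercept, resid, slope_se = _ols(t[start_i : w1 + 1], y[start_i : w1 + 1])
            segments[-1] = Segment(
                float(t[start_i]),
                float(t[w1]),
                slope,
                intercept,
                segment_score(resid, params.score_mode),
                w1 - start_i + 1,
                slope_se,
            )
    return segments, skipped


def segment_trace(trace: Trace, params: SegmentationParams | None = None) -> SegmentationResult:
    """Greedy segmentation of every constant-force phase of ``trace``.

    Each phase's analysis window starts ``settle`` seconds after the
    force change; phases too short for one minimum-length interval are
    reported in no window.
    """
    params = params or SegmentationParams()
    t, y = trace.time, trace.extension
    dt = trace.dt
    nmin = _min_samples(params, dt)
    result = SegmentationResult()
    any_window = False
    for a, b, _f in trace.phases():
        w0 = a + int(np.ceil(params.settle / dt))
        w1 = b - 1
        if w1 - w0 + 1 < nmin:
            continue
        any_window = True
        result.analyzed_windows.append((float(t[w0]), float(t[w1])))
        segs, skips = _segment_window(t, y, w0, w1, params)
        result.segments.extend(segs)
        result.skipped.extend(skips)
    if not any_window:
        warnings.warn("no analysis window of at least min_len after settle; empty result")
    return result


# ---------------------------------------------------------------------------
# exact DP oracle (tests only)


def dp_segment(
    trace: Trace,
    params: SegmentationParams | None = None,
    max_segments: int = 5,
    max_samples: int = 2000,
) -> SegmentationResult:
    """Exact minimum-total-score partition of the whole trace.

    Dynamic programming over all partitions into at most
    ``max_segments`` contiguous pieces of duration >= ``min_len``.
    O(n^2 * K) score evaluations — a test oracle for the greedy
    segmenter, not a user-facing mode (``settle``/``overlap``/skip
    logic do not apply).
    """
    params = params or SegmentationParams()
    t, y = trace.time, trace.extension
    n = len(t)
    if n > max_samples:
        raise ValueError(f"dp_segment is O(n^2 K); n={n} exceeds max_samples={max_samples}")
    dt = trace.dt
    nmin = _min_samples(params, dt)
    if n < nmin:
        raise ValueError("trace shorter than one minimum-length segment")

    # piece score for span [i, j] inclusive
    cache: dict[tuple[int, int], tuple[float, float, float, float]] = {}

    def piece(i: int, j: int):
        key = (i, j)
        if key not in cache:
            slope, intercept, resid, slope_se = _ols(t[i : j + 1], y[i : j + 1])
            cache[key] = (segment_score(resid, params.score_mode), slope, intercept, slope_se)
        return cache[key]

    INF = float("inf")
    # best[k][j] = min total score partitioning samples [0, j] into exactly k pieces
    best = np.full((max_segments + 1, n), INF)
    back = np.full((max_segments + 1, n), -1, dtype=int)
    for j in range(nmin - 1, n):
        best[1][j] = piece(0, j)[0]
        back[1][j] = 0
    for k in range(2, max_segments + 1):
        for j in range(k * nmin - 1, n):
            lo = (k - 1) * nmin  # first sample of the last piece
            hi = j - nmin + 1
            for i in range(lo, hi + 1):
                prev = best[k - 1][i - 1]
                if prev == INF:
                    continue
                tot = prev + piece(i, j)[0]
                if tot < best[k][j] - _SCORE_TIE_ATOL:
                    best[k][j] = tot
                    back[k][j] = i
    # minimum total score; ties (within tolerance) go to the fewest pieces
    finals = best[1:, n - 1]
    best_score = float(np.min(finals))
    k_best = 1 + int(np.argmax(finals <= best_score + _SCORE_TIE_ATOL))
    result = SegmentationResult(analyzed_windows=[(float(t[0]), float(t[n - 1]))])
    bounds = []
    j = n - 1
    for k in range(k_best, 0, -1):
        i = back[k][j]
        bounds.append((i, j))
        j = i - 1
    for i, j in reversed(bounds):
        sc, slope, intercept, slope_se = piece(i, j)
        result.segments.append(
            Segment(float(t[i]), float(t[j]), slope, intercept, sc, j - i + 1, slope_se)
        )
    return result


# ---------------------------------------------------------------------------
# estimator facade


class GreedySegmenter(BaseEstimator):
    """Scikit-learn-style wrapper around the greedy segmenter.

    Parameters mirror :class:`SegmentationParams`. ``fit`` consumes a
    :class:`~smtrace.simulate.Trace` and exposes the fitted pieces as
    ``segments_`` / ``result_``.
    """

    def __init__(
        self,
        min_len: float = 2.0,
        skip_max: float = 1.0,
        overlap: float = 0.5,
        settle: float = 20.0,
        skip_zscore: float = 3.0,
        score_mode: str = "robust",
    ):
        self.min_len = min_len
        self.skip_max = skip_max
        self.overlap = overlap
        self.settle = settle
        self.skip_zscore = skip_zscore
        self.score_mode = score_mode

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            min_len=self.min_len,
            skip_max=self.skip_max,
            overlap=self.overlap,
            settle=self.settle,
            skip_zscore=self.skip_zscore,
            score_mode=self.score_mode,
        )

    def fit(self, trace: Trace, y=None) -> "GreedySegmenter":
        if not isinstance(trace, Trace):
            raise TypeError("GreedySegmenter.fit expects a Trace")
        self.result_ = segment_trace(trace, self._params())
        self.segments_ = self.result_.segments
        self.n_segments_ = len(self.segments_)
        return self

    def transform(self, trace: Trace) -> np.ndarray:
        """Per-segment (t_start, t_end, slope) array for the fitted trace."""
        if not hasattr(self, "result_"):
            raise RuntimeError("call fit first")
        return np.array([[s.t_start, s.t_end, s.slope] for s in self.segments_])

    def fit_transform(self, trace: Trace, y=None) -> np.ndarray:
        return self.fit(trace).transform(trace)
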