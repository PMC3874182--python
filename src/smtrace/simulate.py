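"""Seeded synthetic magnetic-tweezers traces with ground-truth labels.

Emulates constant-force binding experiments (nucleoprotein filaments
extending a dsDNA tether in discrete, pausing increments), homologous
strand-exchange elongation, naked-DNA controls, and force-ramp
calibration pulls. Every trace is reproducible from an integer seed and
carries the exact breakpoints, slopes and pause levels the generator
realised, so the analysis stages can be validated without lab data.

Units are nm, s, pN throughout. Sampling is 5 Hz (dt = 0.2 s) with
i.i.d. Gaussian position noise of 10 nm by default, matching typical
camera-limited bead tracking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mechanics import MechanicsParams, force_extension

__all__ = [
    "FilamentSpec",
    "ForcePhase",
    "ForceProtocol",
    "BindingKinetics",
    "NoiseModel",
    "Trace",
    "GroundTruth",
    "simulate_binding_trace",
    "simulate_exchange_trace",
    "simulate_control_trace",
    "simulate_overstretch_ramp",
    "simulate_cohort",
    "standard_binding_protocol",
    "standard_exchange_protocol",
]

LAMBDA_BP = 48502  # lambda phage dsDNA construct size
FORCE_MIN, FORCE_MAX = 2.0, 200.0  # instrument force range, pN

PULLING_MODES = ("3p5p", "3p3p", "5p5p")
TARGET_STRANDS = ("complementary", "outgoing", "none")

# Phenomenological nucleation thresholds per pulling geometry: filaments
# extend 3'5'-pulled dsDNA from ~50 pN up, while 3'3'/5'5' pulling shows
# no extension anywhere in the studied <=58 pN range, so its effective
# threshold lies above it.
DEFAULT_THRESHOLDS = {"3p5p": 50.0, "3p3p": 60.0, "5p5p": 60.0}


@dataclass(frozen=True)
class FilamentSpec:
    """A recombinase–ssDNA filament available for binding.

    ``ext_per_nt`` is the extension the tether gains per filament
    nucleotide once fully bound (0.12 nm/nt for Rad51; RecA's reference
    value is 0.17 nm/nt).
    """

    length_nt: int = 700
    homologous: bool = False
    ext_per_nt: float = 0.12
    target_strand: str = "none"

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError("length_nt must be positive")
        if self.ext_per_nt <= 0:
            raise ValueError("ext_per_nt must be positive")
        if self.target_strand not in TARGET_STRANDS:
            raise ValueError(f"target_strand must be one of {TARGET_STRANDS}")
        if (self.target_strand == "none") != (not self.homologous):
            raise ValueError("target_strand is 'none' iff the filament is non-homologous")

    @property
    def full_extension(self) -> float:
        """Extension gain of one fully bound filament, nm."""
        return self.length_nt * self.ext_per_nt


@dataclass(frozen=True)
class ForcePhase:
    duration: float  # s
    force: float  # pN

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if not FORCE_MIN <= self.force <= FORCE_MAX:
            raise ValueError(f"force {self.force} pN outside instrument range")


@dataclass(frozen=True)
class ForceProtocol:
    """Ordered constant-force phases applied to the tether."""

    phases: tuple[ForcePhase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def change_times(self) -> list[float]:
        """Times of force steps, excluding t=0 and the end."""
        t, out = 0.0, []
        for p in self.phases[:-1]:
            t += p.duration
            out.append(t)
        return out

    def force_at(self, t: float) -> float:
        acc = 0.0
        for p in self.phases:
            acc += p.duration
            if t < acc:
                return p.force
        return self.phases[-1].force

    def sample(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        n = int(round(self.total_duration / dt))
        time = np.arange(n) * dt
        force = np.empty(n)
        start = 0.0
        for p in self.phases:
            mask = (time >= start - 1e-9) & (time < start + p.duration - 1e-9)
            force[mask] = p.force
            start += p.duration
        return time, force


def standard_binding_protocol(test_force: float, hold: float = 120.0) -> ForceProtocol:
    """40 pN hold, step to the test force, release back to 40 pN (120 s each)."""
    return ForceProtocol(
        (ForcePhase(hold, 40.0), ForcePhase(hold, test_force), ForcePhase(hold, 40.0))
    )


def standard_exchange_protocol(force: float = 25.0, hold: float = 120.0) -> ForceProtocol:
    """Single constant-force phase in the 20–35 pN strand-exchange regime."""
    return ForceProtocol((ForcePhase(hold, force),))


@dataclass(frozen=True)
class BindingKinetics:
    """Filament binding/unbinding kinetics for a pulling geometry.

    Nucleation is a Poisson process gated by force: zero below the
    mode's threshold, ``nucleation_rate`` at or above it. Nucleation is
    sequential — a new filament can nucleate only while the tether sits
    at a pause level, which is what produces pause ladders at integer
    multiples of the filament length. When the force drops below
    threshold the (non-homologous) dsDNA unbinds and the extension gain
    relaxes to zero at ``release_speed``.
    """

    mode: str = "3p5p"
    nucleation_rate: float = 0.1  # events/s above threshold
    threshold_force: float | None = None  # pN; default per mode
    growth_speed: float = 2.0  # nm/s while a filament is binding
    release_speed: float = 10.0  # nm/s while unbinding
    pause_at_full_filament: bool = True
    forced_nucleation_times: tuple[float, ...] | None = None  # deterministic override, s

    def __post_init__(self) -> None:
        if self.mode not in PULLING_MODES:
            raise ValueError(f"mode must be one of {PULLING_MODES}")
        if self.nucleation_rate < 0 or self.growth_speed < 0 or self.release_speed < 0:
            raise ValueError("rates and speeds must be non-negative")
        thr = self.effective_threshold
        if not FORCE_MIN <= thr <= FORCE_MAX:
            raise ValueError("threshold force outside instrument range")

    @property
    def effective_threshold(self) -> float:
        if self.threshold_force is not None:
            return self.threshold_force
        return DEFAULT_THRESHOLDS[self.mode]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model: Gaussian position noise on a uniform grid."""

    sigma: float = 10.0  # nm
    dt: float = 0.2  # s
    drift_rate: float = 0.0  # nm/s
    bead_force_cv: float = 0.05  # bead-to-bead force scatter (calibration studies)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class Trace:
    """Uniformly sampled extension/force time series."""

    time: np.ndarray  # s
    extension: np.ndarray  # nm
    force: np.ndarray  # pN (nominal, i.e. as recorded by the instrument)
    construct_bp: int = LAMBDA_BP
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time, extension and force must have equal length")
        if len(self.time) < 2:
            raise ValueError("trace needs at least two samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.extension)):
            raise ValueError("extension must be finite")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0] + self.dt)

    def phases(self, force_tol: float = 0.05) -> list[tuple[int, int, float]]:
        """Maximal constant-force runs as (start, stop, force) index spans."""
        jumps = np.flatnonzero(np.abs(np.diff(self.force)) > force_tol) + 1
        bounds = [0, *jumps.tolist(), len(self.force)]
        return [
            (a, b, float(np.median(self.force[a:b])))
            for a, b in zip(bounds[:-1], bounds[1:])
        ]


@dataclass
class GroundTruth:
    """Exact labels of the noiseless signal underlying a synthetic trace."""

    breakpoints: list[float]  # s; every slope change / force step
    segment_slopes: list[float]  # nm/s between consecutive breakpoints
    pause_levels: list[float]  # nm above baseline, integer filament multiples
    n_filaments_bound: int = 0

    def __post_init__(self) -> None:
        if sorted(self.breakpoints) != list(self.breakpoints):
            raise ValueError("breakpoints must be sorted")
        if len(self.segment_slopes) != len(self.breakpoints) + 1:
            raise ValueError("need exactly len(breakpoints)+1 slopes")

    def to_dict(self) -> dict:
        return {
            "breakpoints": list(map(float, self.breakpoints)),
            "segment_slopes": list(map(float, self.segment_slopes)),
            "pause_levels": list(map(float, self.pause_levels)),
            "n_filaments_bound": int(self.n_filaments_bound),
        }


# ---------------------------------------------------------------------------
# internal: continuous-time piecewise-linear extension-gain signal


def _binding_knots(
    protocol: ForceProtocol,
    filament: FilamentSpec,
    kinetics: BindingKinetics,
    n_filaments_max: int,
    rng: np.random.Generator,
    bead_scale: float,
):
    """Event-driven construction of the extension-gain signal dL(t).

    Returns knot times/values of the piecewise-linear dL plus the pause
    levels visited (with positive dwell) and the final filament count.
    """
    full = filament.full_extension
    thr = kinetics.effective_threshold
    forced = None
    if kinetics.forced_nucleation_times is not None:
        forced = sorted(kinetics.forced_nucleation_times)

    knot_t, knot_v = [0.0], [0.0]
    pause_levels: list[float] = []
    t, dl, k = 0.0, 0.0, 0  # k = filaments fully bound
    k_max = 0
    growing = False
    phase_start = 0.0

    def emit(tt: float, vv: float) -> None:
        if tt > knot_t[-1] + 1e-12:
            knot_t.append(tt)
            knot_v.append(vv)

    def next_nucleation(now: float) -> float:
        if forced is not None:
            for ft in forced:
                if ft >= now - 1e-12:
                    return ft
            return math.inf
        if kinetics.nucleation_rate <= 0:
            return math.inf
        return now + rng.exponential(1.0 / kinetics.nucleation_rate)

    for phase in protocol.phases:
        phase_end = phase_start + phase.duration
        true_force = phase.force * bead_scale
        if true_force >= thr:
            # binding-permissive phase
            while t < phase_end - 1e-12:
                if growing:
                    target = (k + 1) * full
                    if kinetics.growth_speed <= 0:
                        t = phase_end
                        break
                    t_done = t + (target - dl) / kinetics.growth_speed
                    if t_done <= phase_end:
                        emit(t_done, target)
                        t, dl, k = t_done, target, k + 1
                        k_max = max(k_max, k)
                        growing = False
                        if k < n_filaments_max and not kinetics.pause_at_full_filament:
                            growing = True
                        elif k < n_filaments_max:
                            pause_levels.append(dl)
                    else:
                        dl += kinetics.growth_speed * (phase_end - t)
                        t = phase_end
                else:
                    if k >= n_filaments_max:
                        if dl > 0 and dl not in pause_levels:
                            pause_levels.append(dl)
                        t = phase_end
                        break
                    t_nuc = next_nucleation(t)
                    if t_nuc < phase_end:
                        emit(t_nuc, dl)
                        t = t_nuc
                        growing = True
                    else:
                        t = phase_end
            emit(phase_end, dl)
        else:
            # below threshold: non-homologous filaments release
            emit(phase_start, dl)
            growing = False
            if dl > 0 and not filament.homologous and kinetics.release_speed > 0:
                t_zero = phase_start + dl / kinetics.release_speed
                if t_zero <= phase_end:
                    emit(t_zero, 0.0)
                    dl, k = 0.0, 0
                else:
                    dl -= kinetics.release_speed * (phase_end - phase_start)
                    # partial release; filaments partially detached
            emit(phase_end, dl)
            t = phase_end
        phase_start = phase_end

    # terminal pause level if the trace ends on a completed filament
    if not growing and dl > 0 and dl not in pause_levels and abs(dl / full - round(dl / full)) < 1e-9:
        pause_levels.append(dl)
    return knot_t, knot_v, sorted(set(pause_levels)), k_max


def _ground_truth_from_knots(
    time: np.ndarray,
    knot_t: list[float],
    knot_v: list[float],
    change_times: list[float],
    pause_levels: list[float],
    n_bound: int,
) -> GroundTruth:
    end = float(time[-1])
    bps = sorted({round(t, 9) for t in (knot_t[1:] + change_times) if 1e-9 < t < end - 1e-9})
    slopes = []
    edges = [0.0, *bps, end]
    for a, b in zip(edges[:-1], edges[1:]):
        mid0 = a + 0.25 * (b - a)
        mid1 = a + 0.75 * (b - a)
        v0 = np.interp(mid0, knot_t, knot_v)
        v1 = np.interp(mid1, knot_t, knot_v)
        slopes.append(float((v1 - v0) / (mid1 - mid0)) if b > a else 0.0)
    return GroundTruth(bps, slopes, pause_levels, n_bound)


def _finalize(
    protocol: ForceProtocol,
    gain: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator,
    construct_bp: int,
    mechanics: MechanicsParams,
    bead_scale: float,
    meta: dict,
) -> Trace:
    time, nominal_force = protocol.sample(noise.dt)
    baseline = force_extension(nominal_force * bead_scale, construct_bp, mechanics)
    ext = baseline + gain
    if noise.drift_rate:
        ext = ext + noise.drift_rate * time
    if noise.sigma > 0:
        ext = ext + rng.normal(0.0, noise.sigma, size=len(time))
    return Trace(time, ext, nominal_force, construct_bp, meta)


# ---------------------------------------------------------------------------
# public generators


def simulate_binding_trace(
    protocol: ForceProtocol,
    filament: FilamentSpec,
    kinetics: BindingKinetics,
    noise: NoiseModel,
    n_filaments_max: int = 5,
    seed: int | np.random.SeedSequence = 0,
    mechanics: MechanicsParams | None = None,
    construct_bp: int = LAMBDA_BP,
    bead_scale: float = 1.0,
) -> tuple[Trace, GroundTruth]:
    """Simulate a constant-force filament-binding experiment.

    The tether extension is the naked-DNA baseline at the current force
    plus a piecewise-linear binding gain: Poisson-nucleated filaments
    each add ``length_nt * ext_per_nt`` nm at ``growth_speed``, pausing
    at integer multiples of the filament length between nucleations, and
    releasing at ``release_speed`` once the force drops below the mode
    threshold.
    """
    if n_filaments_max < 1:
        raise ValueError("n_filaments_max must be >= 1")
    mechanics = mechanics or MechanicsParams()
    rng = np.random.default_rng(seed)
    knot_t, knot_v, pauses, k = _binding_knots(
        protocol, filament, kinetics, n_filaments_max, rng, bead_scale
    )
    time, _ = protocol.sample(noise.dt)
    gain = np.interp(time, knot_t, knot_v)
    gt = _ground_truth_from_knots(time, knot_t, knot_v, protocol.change_times, pauses, k)
    meta = {
        "kind": "binding",
        "seed": _seed_repr(seed),
        "mode": kinetics.mode,
        "filament_nt": filament.length_nt,
        "construct_bp": construct_bp,
    }
    trace = _finalize(protocol, gain, noise, rng, construct_bp, mechanics, bead_scale, meta)
    return trace, gt


def simulate_exchange_trace(
    rate: float,
    protocol: ForceProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    mechanics: MechanicsParams | None = None,
    construct_bp: int = LAMBDA_BP,
    pulled_strand: str = "outgoing",
) -> tuple[Trace, GroundTruth]:
    """Simulate strand-exchange elongation of a homologous joint molecule.

    The extension grows linearly at ``rate`` nm/s for the whole
    protocol; homologous joints are stable, so nothing releases when the
    force changes.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    protocol = protocol or standard_exchange_protocol()
    noise = noise or NoiseModel()
    mechanics = mechanics or MechanicsParams()
    rng = np.random.default_rng(seed)
    time, _ = protocol.sample(noise.dt)
    gain = rate * time
    end = float(time[-1])
    knot_t = [0.0, end]
    knot_v = [0.0, rate * end]
    gt = _ground_truth_from_knots(time, knot_t, knot_v, protocol.change_times, [], 1)
    meta = {
        "kind": "exchange",
        "seed": _seed_repr(seed),
        "pulled_strand": pulled_strand,
        "rate_nm_per_s": rate,
        "construct_bp": construct_bp,
    }
    return _finalize(protocol, gain, noise, rng, construct_bp, mechanics, 1.0, meta), gt


def simulate_control_trace(
    protocol: ForceProtocol,
    noise: NoiseModel,
    seed: int | np.random.SeedSequence = 0,
    mechanics: MechanicsParams | None = None,
    construct_bp: int = LAMBDA_BP,
    settle_amplitude: float = 0.0,
    settle_tau: float = 5.0,
) -> Trace:
    """Naked-DNA (or filament-free) control: baseline plus noise.

    ``settle_amplitude`` adds a short exponential settling transient
    (time constant ``settle_tau`` s, negligible after ~20 s) after each
    force change, emulating instrument re-equilibration.
    """
    mechanics = mechanics or MechanicsParams()
    rng = np.random.default_rng(seed)
    time, _ = protocol.sample(noise.dt)
    gain = np.zeros_like(time)
    if settle_amplitude:
        for tc in [0.0, *protocol.change_times]:
            after = time >= tc - 1e-9
            gain[after] += settle_amplitude * np.exp(-(time[after] - tc) / settle_tau)
    meta = {"kind": "control", "seed": _seed_repr(seed), "construct_bp": construct_bp}
    return _finalize(protocol, gain, noise, rng, construct_bp, mechanics, 1.0, meta)


def simulate_overstretch_ramp(
    bead_scale: float = 1.0,
    params: MechanicsParams | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    f_start: float = 2.0,
    f_end: float = 80.0,
    ramp_rate: float = 0.65,
    construct_bp: int = LAMBDA_BP,
) -> Trace:
    """Force ramp through the overstretching transition for calibration.

    The *true* force on the bead ramps linearly from ``f_start`` to
    ``f_end`` pN at ``ramp_rate`` pN/s; the recorded (nominal) force is
    true force / ``bead_scale``, emulating a bead whose magnetization
    differs from the assumed one. The model is memoryless, so forward
    and reverse ramps give the same curve.
    """
    if bead_scale <= 0:
        raise ValueError("bead_scale must be positive")
    if ramp_rate == 0 or f_end == f_start:
        raise ValueError("ramp must change force")
    params = params or MechanicsParams()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    duration = abs(f_end - f_start) / abs(ramp_rate)
    n = int(round(duration / noise.dt))
    time = np.arange(n) * noise.dt
    true_force = np.linspace(f_start, f_end, n)
    ext = force_extension(true_force, construct_bp, params)
    if noise.sigma > 0:
        ext = ext + rng.normal(0.0, noise.sigma, size=n)
    meta = {
        "kind": "overstretch_ramp",
        "seed": _seed_repr(seed),
        "bead_scale": bead_scale,
        "construct_bp": construct_bp,
    }
    return Trace(time, ext, true_force / bead_scale, construct_bp, meta)


# ---------------------------------------------------------------------------
# cohorts


def _seed_repr(seed) -> int | str:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] % (2**31))
    return int(seed)


def simulate_cohort(
    config: dict,
    seed: int | np.random.SeedSequence = 0,
) -> list[tuple[Trace, GroundTruth | None]]:
    """Generate a reproducible cohort of traces from a config mapping.

    ``config['cohorts']`` is a list of group dicts, each with a ``kind``
    (``binding``/``exchange``/``control``/``ramp``), ``replicates`` and
    kind-specific fields (``mode``, ``force``, ``filament_nt``, ``rate``,
    ``pulled_strand``, ``bead_scale`` ...). Per-trace seeds are spawned
    deterministically from the master seed.
    """
    groups = config.get("cohorts")
    if not groups:
        raise ValueError("config must define a non-empty 'cohorts' list")
    noise_cfg = config.get("noise", {})
    noise = NoiseModel(**noise_cfg)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out: list[tuple[Trace, GroundTruth | None]] = []
    for gi, group in enumerate(groups):
        kind = group.get("kind")
        reps = int(group.get("replicates", 1))
        if reps < 1:
            raise ValueError("replicates must be >= 1")
        # spawn per-group then per-trace so group order is part of the stream
        group_seed = np.random.SeedSequence(
            entropy=master.entropy, spawn_key=(*master.spawn_key, gi)
        )
        children = group_seed.spawn(reps)
        for ri, child in enumerate(children):
            if kind == "binding":
                filament = FilamentSpec(
                    length_nt=int(group.get("filament_nt", 700)),
                    homologous=bool(group.get("homologous", False)),
                    ext_per_nt=float(group.get("ext_per_nt", 0.12)),
                    target_strand=group.get("target_strand", "none"),
                )
                kin = BindingKinetics(
                    mode=group.get("mode", "3p5p"),
                    nucleation_rate=float(group.get("nucleation_rate", 0.1)),
                    threshold_force=group.get("threshold_force"),
                    growth_speed=float(group.get("growth_speed", 2.0)),
                    release_speed=float(group.get("release_speed", 10.0)),
                )
                protocol = standard_binding_protocol(float(group.get("force", 56.0)))
                trace, gt = simulate_binding_trace(
                    protocol,
                    filament,
                    kin,
                    noise,
                    n_filaments_max=int(group.get("n_filaments_max", 5)),
                    seed=child,
                )
            elif kind == "exchange":
                protocol = standard_exchange_protocol(float(group.get("force", 25.0)))
                trace, gt = simulate_exchange_trace(
                    float(group.get("rate", 0.0)),
                    protocol,
                    noise,
                    seed=child,
                    pulled_strand=group.get("pulled_strand", "outgoing"),
                )
            elif kind == "control":
                protocol = standard_binding_protocol(float(group.get("force", 56.0)))
                trace = simulate_control_trace(protocol, noise, seed=child)
                gt = None
            elif kind == "ramp":
                trace = simulate_overstretch_ramp(
                    bead_scale=float(group.get("bead_scale", 1.0)),
                    noise=noise,
                    seed=child,
                )
                gt = None
            else:
                raise ValueError(f"unknown cohort kind {kind!r}")
            trace.meta["group"] = gi
            trace.meta["replicate"] = ri
            for key in ("mode", "force", "filament_nt", "pulled_strand", "rate"):
                if key in group:
                    trace.meta.setdefault(key, group[key])
            out.append((trace, gt))
    return out
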