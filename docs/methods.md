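# Methods

Units are nm, s, pN throughout. All randomness flows through numpy
`SeedSequence`s; identical seeds give identical outputs.

## dsDNA mechanics model

The naked-DNA baseline is a phenomenological force–extension law

    x(F) = L0 · [ 1 + c·F + (k − 1) · S(F) ],      L0 = n_bp · 0.34 nm

with compliance `c = 3·10⁻⁴ /pN` (shallow enthalpic stretching of
B-DNA below the transition), overstretch factor `k = 1.7`, and `S` a
logistic occupancy of the overstretched state centred at 65 pN. The
"width" quoted everywhere is the 10–90% rise of the logistic
(2 ln 9 ≈ 4.39 scale units), default 2 pN. Only these features — B-form
plateau, transition midpoint/width, 1.7× overstretched plateau — matter
to the analysis, so no worm-like-chain elasticity is modelled. The
model is memoryless (no overstretching hysteresis) and monotone
non-decreasing in force.

## Synthetic traces

`simulate_binding_trace` adds to that baseline a piecewise-linear
binding gain ΔL(t) built event-by-event in continuous time:

- **Nucleation** is a Poisson process, active only while the applied
  force is at or above a pulling-geometry threshold (50 pN for 3′5′
  pulling; 60 pN — i.e. above the studied ≤58 pN range — for 3′3′ and
  5′5′, which never extend in that range) and only while the trace sits
  at a pause level. This sequential rule (no nucleation during growth)
  is what produces clean pause ladders at integer multiples of the
  filament length.
- **Growth** proceeds at 2 nm/s until ΔL reaches k × N × g, where N is
  the filament length in nt and g the extension per nucleotide
  (default 0.12 nm/nt), then pauses until the next nucleation, up to
  `n_filaments_max` (default 5) filaments.
- **Release**: when the force drops below threshold, non-homologous
  dsDNA unbinds and ΔL relaxes to zero at 10 nm/s. Homologous joints
  are stable and do not release.

Nucleation rate, growth and release speeds are free parameters of the
generator — the experiments constrain outcomes, not kinetics. Two
regimes are used by the study presets: **rare** binding
(0.02 events/s, mean wait 50 s) for pause-ladder studies, because pause
points exist only when dwells at completed filaments last long enough
to segment (≫ the 2 s minimum interval), and **abundant** binding
(0.1 events/s) for extension-vs-force selectivity studies, where traces
climb several filament lengths within the 120 s phase.

Measurement noise is i.i.d. Gaussian per 0.2 s sample (σ = 10 nm),
optionally with linear drift; no bead-fluctuation spectrum is modelled.
Bead-to-bead magnetization scatter (cv 5%) enters calibration studies
through an explicit `bead_scale`: the recorded (nominal) force is the
true force divided by the bead's scale. Binding and exchange
simulations default to calibrated beads (`bead_scale = 1`).

Exchange traces grow linearly at the given rate for the whole
constant-force phase (20–35 pN regime, default 25 pN / 120 s).
Ground-truth sidecars carry every breakpoint, per-interval slope, pause
level and the bound-filament count.

What the generator deliberately does **not** emulate: bead-tracking
artifacts, low-frequency drift spectra, force-dependent growth speeds,
partial filament binding, torque or supercoiling. Passing tests
demonstrate correct *recovery of the generator's own structure* at
realistic noise; they do not certify performance on instrument
pathologies absent from the model.

## Segmentation

Given samples on a uniform grid, analysis windows start 20 s after each
force change (detected from the force column) and end with the phase.
From the window start every candidate end giving a duration ≥ 2 s is
fit by OLS and scored by

    score = mean(|eᵢ|) · mean_{k=1..n−1}(|ρ_k|),

ρ_k the biased lag-k autocorrelation of the residuals. On featureless
(white-noise) residuals mean|ρ_k| ≈ √(2/(πn)) decays with interval
length, so long homogeneous fits win; crossing a growth-rate change
inflates both factors sharply. The minimum-score candidate is kept
(ties within 10⁻¹⁰, which arise only for exact fits, go to the longest
candidate), and the search restarts 0.5 s before the accepted endpoint.
A trailing remainder shorter than the minimum interval is merged into
the final segment so segments tile the window.

Two notes on the score family. A *signed* residual sum is identically
zero for intercept-OLS fits, and the biased autocorrelations of any
such residual sequence sum to exactly −½ (both follow from Σeᵢ = 0), so
the literal product |Σeᵢ|/n · Σρ_k degenerates to zero for every
candidate; it is retained behind `score_mode="literal"` for comparison
only. And an *unnormalized* absolute lag sum Σ|ρ_k| grows like √n on
white noise, which would drive the greedy search toward minimum-length
segments; dividing by the number of lags is what makes the score favor
long homogeneous intervals.

**High-noise skips.** Before fitting, each window is scanned for brief
noise bursts: the local trend is a running median (kernel ≈ the
minimum interval), the noise scale σ̂ comes from second differences
(1.4826·MAD/√6, immune to piecewise-linear trend), and runs where
|y − trend|/σ̂ > 3 qualify as skips if they last < 1 s and carry total
excess z-mass ≥ 3 (so isolated borderline samples are not flagged).
Skipped samples are excluded from all fits and logged. If σ̂ ≈ 0
(noiseless data) nothing is skipped.

**DP oracle.** `dp_segment` minimizes the total score exactly over all
partitions into ≤ K contiguous pieces of admissible length
(O(n²K), tests only). On noiseless piecewise-linear input a zero total
is attainable only at the true knots, so both greedy and DP must
recover every knot within one sample; on any input the DP total is a
lower bound on the greedy total. Oracle comparisons run with zero
overlap, since the DP is a strict partition.

## Binding observables

ΔL is the mean extension over a window 105–120 s after the step to the
test force, minus a baseline measured on the same molecule: the mean
extension over the last 20 s of the preceding 40 pN phase plus the
mechanics model's naked-DNA elastic difference between the two forces
(≈ 79 nm between 40 and 56 pN on a λ construct; switchable to a raw
difference).

Pauses are segments in the high-force phase with |slope| ≤
max(0.02, min(2·SE(slope), 0.5)) nm/s. The absolute cap matters: on a
2–3 s segment at 10 nm noise the slope SE is ~2 nm/s, and "consistent
with zero" alone would admit clearly growing stretches. Pause levels
(segment mean minus baseline) are pooled into a duration-weighted
histogram (10 nm bins ≈ the measurement accuracy; peak prominence
≥ 20% of the tallest bin; peak centers refined as duration-weighted
means within one bin width).

The extension per nucleotide comes from assigning each histogram peak
to an integer multiple of the filament length via a comb fit: candidate
units are scanned over the physically admissible 0.05–0.20 nm/nt range,
the cost is the weighted squared fractional distance of each peak to
its nearest multiple, and among near-tied costs the **largest** unit
wins (a unit u/2 always fits at least as well as u, so subharmonic
combs must be rejected explicitly). Peaks off their multiple by >25%
are dropped. The cohort estimator additionally ignores plateaus
dwelling < 5 s and levels < 20 nm: genuine pause points dwell for tens
of seconds, while brief flat stretches inside a growth ramp sit at no
particular multiple and can derail the comb. Per-length estimates are
pooled weighted by pause count.

Coverage is the ratio of the measured extension per nt to the
0.17 nm/nt fully-coated reference, clipped to 1. Both the
shorter-projection and the incomplete-coverage readings of a value
below 0.17 are left to the user; the package reports the numbers.

## Exchange rates

Each trace contributes the duration-weighted median of its segment
slopes (the dominant growth segment governs; occasional short
end-of-window fits, whose slopes are wild at 10 nm noise, cannot
pollute it). The cohort's characteristic rate is the dominant KDE mode
(Silverman bandwidth) outside a ±0.05 nm/s zero band — ≈3× the
single-trace slope SE at default conditions, so "no exchange" molecules
land in the band — aggregated over a seeded bootstrap across traces:
the point estimate is the mean of the bootstrap mode distribution
(bagging roughly halves the mode's sampling error at cohorts of a few
tens), and the CI is its 2.5/97.5 percentiles. Cohort comparisons
bootstrap the difference of modes; significance means the interval
excludes zero. A Gaussian-mixture alternative was considered and
rejected for instability at n ≈ tens; the slopes are sorted before
resampling so estimates are invariant to trace ordering.

## Calibration

A calibration ramp (2 → 80 pN through the transition) is fit with a
linear-baseline logistic; the fitted midpoint on the nominal force axis
and the 10–90% width are reported, and the bead's correction factor is
65 pN / midpoint. The fit errors out when the transition midpoint is
not comfortably inside the ramp or the step amplitude is not resolved
above noise and baseline slope (e.g. a ramp truncated at 60 pN). At
default noise the recovered scale is within 3% of truth, consistent
with the ±1 pN uncertainty of the 65 pN standard. Calibration is
idempotent: a corrected trace re-calibrates to scale 1.

## Study presets and problem sizes

`smtrace.studies` fixes the cohort designs used for self-validation:
60 binding traces (15 × {400, 700, 1000, 1600} nt, 56 pN, rare
nucleation) for extension-per-nt recovery; 40 exchange traces per
strand cohort (0.21 and 0.12 nm/s presets) for rate recovery; 50
noiseless + 50 noisy piecewise traces (2–4 pieces of 4–8 s) for the
greedy-vs-DP oracle comparison; 8 traces per pulling geometry plus
controls at 56–58 pN for mode selectivity. These sizes give sampling
errors comfortably below the claimed precisions (±0.02 nm/nt, ~10% on
rates) while keeping a full run to a couple of minutes on one core.

## Known limitations

- Breakpoint localization is guaranteed to one sample only on
  noiseless data; at 10 nm noise transitions blur over ~1 s, which is
  why successive intervals may overlap by 0.5 s.
- The KDE-mode rate estimator assumes one dominant nonzero mode;
  strongly multimodal nonzero cohorts should be split by condition
  before estimation.
- The comb fit cannot distinguish a lone peak at 2× the unit from a
  lone peak at the unit if both lie in the admissible range; with the
  ladder's k = 1 peak present this ambiguity does not arise.
- Force is treated as exactly constant within a phase; slow force
  drift would bias baselines through the elastic correction.
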