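# Methods

## Generative observer and experiment simulation

The simulator reproduces the statistical structure the analysis assumes,
not the visual display. An observer judges, on each test trial, whether a
briefly presented background moved with or against the pursuit target. The
decision rule is a cumulative Gaussian around the observer's generative
point of subjective stationarity,

    P(with pursuit | v) = λ/2 + (1 − λ)·Φ((v − PSS_gen)/σ),
    PSS_gen = (1 − g)·s + c,

with pursuit speed *s*, background velocity *v* (pursuit-relative: positive
= same direction as pursuit), compensation gain *g*, constant bias *c*,
sensory noise σ (which is also the generative JND) and lapse rate λ. A
gain-mechanism observer has g ≠ 1, c = 0; a shift-mechanism observer g = 1,
c ≠ 0. The control condition is always simulated as calibrated (g = 1,
c = 0) unless overridden, because exposure — not baseline bias — is the
phenomenon of interest. Exposure trials do not update the observer: the
generative parameters are constant within a condition, so the simulation
captures the steady state of recalibration, not its trial-by-trial
dynamics.

### Design defaults (the study conditions)

| parameter | default | unit |
|---|---|---|
| test pursuit speeds | 5.5, 8.5, 11.5 | °/s |
| exposure pursuit speed | 8.5 | °/s |
| exposure background velocity | ±5 | °/s |
| exposure / test trials per exposure session | 140 / 60 | — |
| control sessions | 3 × 60 test trials, run first | — |
| staircase start / step / bound | ±5 / 1 / 12 | °/s |
| background window | 1100–1300 ms after motion onset | ms |
| fixation delay | U(500, 1000) | ms |
| target motion duration | 2400 (eccentricity = 1.2·s) | ms |
| sampling rate | 1000 | Hz |

This yields 1,380 trials in 9 sessions. The staircase uses two interleaved
1-up/1-down tracks of 30 trials per session, starting at +5 and −5 °/s —
the number of tracks is a design choice (standard practice consistent with
the two stated start velocities, giving symmetric sampling around the PSS).
Velocities are clamped at ±12 °/s to prevent lapse-driven runaway; clamp
events are counted. Exposure-trial pursuit directions are balanced within
session and exposure/test trials are fully randomly interleaved; both
points were genuinely open and are resolved toward the least-structured
assumption.

### Eye traces

Gaze follows the target ramp at a fixed oculomotor gain (default 0.95) with
additive Gaussian position noise (SD 0.005°). Catch-up saccades are placed
by a Poisson process (default 0.7 s⁻¹) as Gaussian velocity pulses of 30 ms
(SD 5 ms) with amplitude U(0.5°, 2°) in the pursuit direction — any profile
exceeding the detection thresholds suffices for detector validation, and
this one has a differentiated peak of ≥ 34 °/s at the smallest amplitude.
Blinks occur with per-trial probability 0.05 as invalid runs of
U(100, 300) ms. With the 200 ms background window these rates imply an
expected exclusion fraction of ≈ 15–16% of trials, matching the real
experiment's reported average. Every injected event is logged so detector
completeness can be asserted exactly.

What the synthetic traces do *not* emulate: pursuit onset latency and
acceleration, anticipatory drift, post-saccadic oscillations, pupil-size
artifacts, measurement-noise autocorrelation, and any 2D (vertical)
component. Passing preprocessing tests therefore shows the detector/gain
logic is correct for well-behaved pursuit with superimposed ballistic
events, not that it is robust to every real-world artifact.

### Randomness

One root seed; independent named substreams per (observer, session) via
`SeedSequence(seed, spawn_key=(observer, session))`. Full runs are
byte-reproducible for a fixed seed.

## Preprocessing

Velocity is the central difference of position over ±5 ms (11 samples at
1 kHz) with no additional smoothing — adequate noise suppression without
distorting 30 ms saccades; acceleration is the first difference of
velocity. Samples whose stencil touches a blink gap are invalid. Saccades
are runs where |v − baseline| > 22 °/s or |a| > 3800 °/s², with the
baseline taken as the median smooth velocity (over the 200 ms preceding the
background window when available): detection must be baseline-relative
because pursuit itself approaches the velocity threshold at 11.5 °/s. Runs
closer than 20 ms are merged; events shorter than 8 ms are discarded.
Blinks are invalid runs ≥ 20 ms, padded by 50 ms per side before overlap
testing. A trial is excluded when any saccade or blink overlaps the
background window; the flag applies to both the psychophysical and the
eye-movement analysis. Pursuit gain is the mean of valid, saccade-free
window velocity divided by the signed target velocity (ideal tracking
→ +1); a window with no usable samples yields NaN and drops from
summaries.

## Psychometric fitting

Maximum likelihood over pss ∈ [−12, 12] and jnd ∈ [0.05, 20] via bounded
quasi-Newton (L-BFGS-B, ftol 10⁻¹²) from six deterministic multistarts
(pss ∈ {−4, 0, 4} × jnd ∈ {1, 4}); Bernoulli probabilities are clipped to
[10⁻⁹, 1 − 10⁻⁹]. The lapse is fixed at 0.01 by default because
staircase-concentrated data leave the asymptotes nearly unconstrained; a
free-lapse mode bounded to [0, 0.06] is available. Cells need ≥ 3 distinct
velocities and both response categories; otherwise a degenerate-data error
is raised (with separable data the location is unidentified). Left- and
right-pursuit trials are merged on the pursuit-relative axis; per-direction
fits are out of scope.

Monte-Carlo calibration (200 seeds) of a staircase-sampled 60-trial cell at
σ = 2: the PSS error distribution has mean |error| ≈ 0.28 °/s and 95th
percentile ≈ 0.75 °/s — close to the theoretical MLE floor of
σ·√(π/2)/√60 ≈ 0.32 °/s once the staircase's convergence transient is
accounted for. Tests freeze these measured bounds.

## Model comparison

Both candidate models have one free parameter and closed-form least-squares
solutions: 1 − g = Σ s·pss / Σ s² (through-origin regression) and
c = mean(pss). Evidence is BIC = n·ln(RSS/n) + k·ln(n) with k = 1 — the
formula presupposes Gaussian residuals and counts only the structural
parameter — converted to relative weights by the softmax of −ΔBIC/2. RSS is
floored at 10⁻¹² (°/s)² because the BIC diverges at zero RSS; if exactly
one model hits the floor it takes weight 1 (the softmax limit).
Classification is the model with weight > 0.5, with an explicit "tied"
outcome at exactly 0.5. "Averaged-data" fits mean fitting the three
across-observer mean PSS values (n = 3), which reproduces the published
weight-0.99 selections in both exposure conditions. Control profiles are
fit but never classified.

## Group statistics

t statistics are formed from their textbook definitions with two-tailed p
values; zero-variance samples raise rather than return ±∞. The two-way
repeated-measures ANOVA (statsmodels `AnovaRM` behind the module surface)
supports balanced fully-crossed layouts only and applies no sphericity
correction, matching the uncorrected df conventions (2, 58)/(4, 116) for
3 × 3 × 30; unbalanced tables raise and must be imputed upstream.

## Problem sizes

The validation simulations use 30-observer cohorts with 3 speeds × 60
staircase trials per observer and σ = 2 °/s — the scale of the real study's
test-trial data — for parameter recovery, and 200 single-observer seeds for
classification-rate and calibration properties. Trace-based checks use
single sessions (60–180 trials), enough for exclusion-fraction and
pursuit-gain recovery assertions at the stated tolerances.

## Known limitations

- The generative response model is stationary within condition; paradigms
  probing adaptation dynamics need a trial-by-trial learning model.
- The saccade detector emulates a threshold parser; it is not a bit-exact
  reimplementation of any proprietary algorithm, and the psychometric
  routine is a generic MLE, not claimed to replicate any specific fitting
  toolbox bit-exactly.
- Individual-level statistics of the real cohort (e.g. specific t values or
  the 27-of-30 classification counts) depend on the deposited human data
  and are covered here only qualitatively by cohort simulations.
- `ingest` mode consumes the trial-table schema documented in
  `experiment_sim` (one row per trial, pursuit-relative signed velocities);
  external datasets must be mapped to it first.
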