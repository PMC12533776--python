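# Methods

## The measurement model

A trial starts with 3 s of stationary masker noise, the target sentence(s)
play at t = 0 (1.2–2.0 s each, one per ear), and the masker continues for 3 s
after the longest sentence ends. The eye tracker inside the head-mounted
display samples the right-eye pupil diameter at a nominal 90 Hz tied to the
rendering frame rate, so the inter-sample interval jitters; samples taken with
the eyes closed arrive flagged ("marked").

The synthetic generator models one trial as

    d(t) = B_trial + A_trial · g(t) + ε_sample(t)

* `B_trial` (baseline, mm) and `A_trial` (dilation amplitude, mm) each follow a
  random-intercept linear model over the 2×2 design (treatment coding,
  reference cell: single-sentence load with distractor copresence):
  `B = x'β_B + b_B + e_B`, `b_B ~ N(0, τ_B²)`, `e_B ~ N(0, σ_B²)`, and
  analogously for `A`. Baseline and amplitude components are independent — no
  baseline–amplitude correlation is modelled because none is assumed by the
  analysis.
* `g(t)` is a gamma-density-shaped pulse, zero for t ≤ 0, normalised so
  `g(t_peak) = 1` with `t_peak = 2.75 s` (configurable within the observed
  2.5–3 s latency band) and shape 4. The unit peak makes amplitude parameters
  directly interpretable as peak pupil dilation in mm. The shape is a
  modelling convenience: only the peak location and unimodality matter
  downstream, not the exact rise/decay.
* Blinks are a Poisson process (0.25 /s) with lognormal durations (mean 0.20 s,
  log-SD 0.4); marks equal the blink interval exactly, and marked samples carry
  no diameter reading. Vendor mark behaviour beyond "eyes closed" is unknown,
  so no separate mark-lag model is attempted.
* Measurement noise is white, SD 0.02 mm.

Default fixed effects are the published estimates: BPS
(4.52, 0.32, 0.07, −0.08) mm and PPD amplitude (0.29, 0.18, −0.02, −0.01) mm
for (intercept, load, copresence, interaction). Variance components are
**calibration defaults**, not published values: τ_B = 0.8 mm and σ_B = 0.45 mm
reproduce the reported BPS CI widths at 33 participants; τ_A = 0.18 mm and
σ_A = 0.14 mm do the same for the PPD column. Subjective ratings use the
published per-rating fixed effects with participant and residual SDs of 1.0
rating point, clipped to the 1–10 scale (stored unrounded so that zero-noise
configurations reproduce linear predictors exactly; one-decimal rounding is
available via `round_ratings`).

Word-repetition accuracy is per-word Bernoulli: 0.97 in single-sentence
conditions (near ceiling), 0.80 / 0.53 for the left / right sentence in dual
conditions. Agent feedback follows the stated rules: eligibility first (full
sentence correct → positive in single; ≥ 2 words from both sentences →
positive in dual; otherwise negative), then a 15 % display draw per agent
(80 % for negative after a single-sentence error), capped at 3 negative and
5 positive animations per agent per condition. The 15 %-before-vs-after
eligibility question is resolved as eligibility-first. Distractor conditions
never receive feedback; if the two agents were ever to disagree the trial is
scored negative (conservative).

Reproducibility: each participant draws from an independent `SeedSequence`
substream, so enlarging a study never perturbs existing participants.

### What the generator does not emulate

Luminance changes, gaze and vergence, head movement, pupil foreshortening,
left-eye data, serial correlation within a trace beyond the pulse, drift or
fatigue across trials, and any dependence of blinks on task phase. Passing
tests therefore demonstrate that the *pipeline* is correct and the *inference*
calibrated under the assumed data-generating process — not that real HMD
recordings satisfy those assumptions.

## Cleaning chain

Order: trace QC → condition QC → blink-margin extension → 60 Hz regrid →
interpolation → BPS → baseline correction → smoothing → drop first four
trials → crop.

* **QC** uses raw marks (before margin extension): a trace is removed iff
  strictly more than 20 % of its samples are marked; a condition is removed
  when ≥ 6 of its 30 traces are. The threshold basis (raw vs extended marks)
  is configurable; raw is the default because exclusion is described before
  de-blinking.
* **Margins** operate in continuous time (83 ms before a marked run, 133 ms
  after), then map back to samples — sampling-rate independent, clipped at the
  trace ends.
* **Regridding** builds the grid −3.0, −3.0 + 1/60, … s; values are linear
  interpolations of the bracketing source samples and a grid point inherits a
  mark from either bracket. Regridding before interpolation (one canonical
  order) is equivalent to the reverse on piecewise-affine signals.
* **Interpolation** replaces interior marked runs with the chord between the
  nearest unmarked neighbours; leading/trailing runs hold the nearest unmarked
  value (the original work does not state its edge rule).
* **BPS** is the mean over the half-open window [−1.0, 0.0) s — 60 grid
  points, the sentence-onset sample excluded. Baseline correction subtracts it
  from every sample and is guarded against double application.
* **Smoothing**: centred 11-point moving average; at the edges the window
  shrinks symmetrically so length is preserved and no missing values appear
  (edge handling is unstated in the source; this choice keeps the filter
  unbiased for locally linear signals).
* **Cropping** keeps [−3.0, +4.2] s: 3 s masker lead + 1.2 s shortest
  sentence + 3 s tail = 7.2 s, 433 samples at 60 Hz.

Dropping the first four trials happens after QC and does not count toward the
≥ 6 rule — they are separate mechanisms (instability vs data loss). The chain
is fully deterministic, and adding a constant to every raw diameter leaves the
baseline-corrected output unchanged (the BPS absorbs it), which the tests
exploit as an invariant.

## Outcome metrics

Per participant × condition: pointwise mean of the retained clean traces, BPS
as the mean of per-trial BPS values over the same retained set, PPD as the
maximum of the mean trace over the full window (ties broken to the earliest
time point; in practice the peak lands 2.5–3 s post onset). Performance is the
percentage of words repeated correctly — left sentence only under single load,
words pooled over both sentences under dual load. The feedback re-binning
assigns each agent-condition trial by the feedback shown on trial t−1 of the
same condition, ignores negative-preceded trials, never bins a condition's
first trial, and excludes bins with fewer than six traces.

## Inference

`PupilLMM` fits `y ~ load * copresence + (1 | participant)` (and the
load × previous-feedback analogue) under 0/1 treatment coding. REML fits give
the reported estimates and Wald 95 % CIs (estimate ± 1.96 SE); full-ML refits
feed the likelihood-ratio tests. Estimation is delegated to statsmodels
`MixedLM`; the Satterthwaite denominator degrees of freedom are computed
in-package from the closed-form random-intercept REML profile:
`ν = 2·v² / (∇v' A ∇v)` with `v = Var(ℓ'β̂)`, the gradient taken in
(τ², σ²) by central differences, and `A` the inverse observed REML
information (finite-difference Hessian of the profile log-likelihood, relative
step 1e−4). On a frozen balanced fixture this reproduces lmerTest estimates
and SEs to ~1e−8 and denominator df to ~1e−5; under the null
(33 participants, 1000 replicates) the F-test's size is 0.05 and CI coverage
0.95 within Monte-Carlo error.

Degenerate paths: a perfectly fitted outcome (zero residual variance) returns
exact OLS coefficients with vacuous tests; a singular fit (participant
variance at zero) falls back to pooled OLS with residual df and a logged
warning. Covariate LRTs add the covariate's main effect plus its interactions
with load, copresence and their product — 4 df — and require the covariate to
be constant within participant. Fixed-effect estimates are invariant to row
order and participant relabeling.

## Power analysis

Power is simulated at the condition-summary level (one PPD per participant ×
condition — the unit the analysis models): generative effects 0.20 mm (load)
and 0.025 mm (copresence), no interaction, fitted with the full 2×2 model,
rejection recorded per effect at α = 0.05 against the 80 % target. Condition
residual SD defaults to σ_A/√26 ≈ 0.0275 mm (26 trials averaged after
cleaning). Because the original calculation's variance assumptions are
unpublished, the resulting minimum n depends on these calibrated components
and is reported with its Monte-Carlo SE rather than validated against any
published figure; the test suite checks the procedure's properties instead
(size ≈ α at zero effect, monotonicity in n and effect size, MC SE
= √(p(1−p)/replicates), determinism given the seed).

## Problem sizes used in the checks

Parameter-recovery runs use 500 replicate studies of 33 participants ×
4 conditions at the condition-summary level; null-calibration uses 1000
replicates; power-property checks use 150–300 replicates per grid point.
These sizes put Monte-Carlo error well below the effects being checked while
keeping the default suite quick to run.

## Known limitations

* Exact denominator df of the original analyses (e.g. F(1, 93)) depend on the
  original missing-data pattern and are not reproducible; only the procedure
  is.
* The published minimum-n figure for the power analysis is not verifiable
  without the original variance assumptions.
* The eye tracker's mark criterion and diameter calibration are taken as
  given; no binocular or vendor-format handling.
* Wald CIs are first-order; profile-likelihood CIs are not implemented.
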