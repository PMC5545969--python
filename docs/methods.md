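# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, in the order the pipeline runs.

## Synthetic cohort generator

The generator emulates the three clinical paradigms at 250 Hz (4 ms
samples), in degrees of visual angle relative to screen centre:

* **Fixation stability** — 3 trials of 10 s with a central cross.
* **Pro-saccade** — 40 trials in two blocks of 20; the target steps to one
  of ten locations (±5°, ±10°, ±15° horizontal; ±5°, ±10° vertical), each
  location four times, balanced within block, order pseudo-randomized once
  and shared by all participants.  The step occurs 700 ms into the trial
  (matching the central fixation + gap period of the task) and times out
  after 5,000 ms.
* **Smooth pursuit** — 12 trials of 10 s (6 horizontal, 6 vertical),
  sinusoidal target motion pairing 10°/s with 0.25 Hz and 20°/s with
  0.5 Hz.  The stated target speeds are read as *peak* velocity, the only
  reading under which both (speed, frequency) pairs imply one consistent
  amplitude, A = v/(2πf) ≈ 6.37°; the amplitude is exposed in the trial
  design should a user prefer the mean-speed reading (A = 10°).

A trace is a sum of three components.  (1) An anchor/tracking path with
**minimum-jerk saccades** (position profile 10τ³ − 15τ⁴ + 6τ⁵, duration
2.2·amplitude + 21 ms — a standard main-sequence approximation whose peak
velocity 1.875·A/D comfortably exceeds the 30°/s detection threshold for
amplitudes above ~0.5°).  (2) **Ornstein–Uhlenbeck fixational drift**
(time constant 100 ms) whose stationary SD is the profile's
`fixation_noise_sd`; the OU form keeps sample-to-sample velocity noise far
below the saccade threshold, which white noise at 250 Hz would not.
(3) **Blinks**: 100–300 ms invalid gaps flanked by 20 ms eyelid-artefact
spikes, so blink padding logic is genuinely exercised.

Group behaviour comes from an `OculomotorProfile`.  Fixation trials place
large intrusions (each >2°, ping-ponging between centre and an eccentric
anchor so every event yields exactly one large saccade) and square-wave-jerk
pairs (0.7–1.8° out, a similar-amplitude return 80–220 ms later) at Poisson
rates.  Pro-saccade trials draw a latency and a primary-saccade gain, then
iterate corrective saccades until the residual error is below 0.75°; with
probability `miss_probability` the trial never enters the 1.5° interest
area.  Pursuit trials alternate tracking segments (eye velocity = gain ×
target velocity, plus catch-up saccades at a Poisson rate) with frozen-gaze
non-tracking segments; segment durations are exponential with mean on-time
1.4 s and the off-time scaled to give the profile's tracking fraction.

The two shipped presets were calibrated a priori to the published group
summary statistics where those directly parameterize the generator (e.g.
intrusion rates 0.7 vs 2.5 per 10 s; tracking fractions 0.6 vs 0.4; miss
probabilities 0.06 vs 0.15 giving accuracies 0.94 vs 0.85) and to plausible
oculomotor physiology elsewhere (latencies 160 vs 240 ms, primary gains
0.90 vs 0.75).  Per-subject heterogeneity applies log-normal jitter
(σ = 0.25) to rates and truncated normal jitter to gains, latencies and
fractions.  Cohorts regenerate deterministically from a master seed via
spawned per-subject seed sequences.

What the generator does *not* emulate: realistic 1/f noise spectra, pupil
signals, saccadic undershoot dynamics during pursuit, or the full
heavy-tailed between-subject variance of a clinical cohort.  Passing tests
therefore demonstrate the correctness of the pipeline's computations and
the achievability of group separation under the stated effect sizes — not
clinical performance on real patients.

## Event detection

Velocity is a central difference of the 5-sample-boxcar-smoothed trace
(the boxcar stabilizes 250 Hz finite differences without flattening a
30 ms saccade); acceleration is the derivative of that velocity.  A saccade
is a maximal run with speed > 30°/s OR |acceleration| > 8,000°/s², with
sub-threshold gaps of one sample merged and a minimum duration of 8 ms.
Complementary valid runs ≥ 40 ms are fixations; invalid runs ± 50 ms
padding are blinks.  The minimum durations, merge gap and padding are
conventional parser defaults, declared in `DetectionConfig` rather than
derived.  Saccade endpoint positions are read two samples beyond the
threshold crossings (still outside adjacent events), because the
sub-threshold tails of a small saccade otherwise bias its amplitude low by
up to ~0.1°.  Peak velocity is taken from the *unsmoothed* central
difference, whose error at 250 Hz is a few percent, whereas the smoothed
peak is biased ~25 % low for short saccades.  The first/last
(halfwidth + 1) samples of each valid run carry smoothing edge effects and
are flagged undefined.  Trials whose invalid fraction exceeds 0.3 are
excluded and reported per paradigm.

## Summary metrics

Implemented exactly as defined by the task battery; decisions where the
definitions name an intent rather than a test:

* **Square wave jerks** — "took the gaze back" is operationalized as: the
  return saccade ends closer to the target than the outgoing one did *and*
  its direction is within 45° of the exact opposite.  Pairing is greedy,
  earliest-first, each saccade in at most one pair (prevents double
  counting and makes the brute-force oracle well defined).
* **Maximum fixation duration** — the longest inter-saccade interval with
  blink time excised: consecutive fixations separated only by a blink are
  merged, the blink itself not counted.
* **Time to fixate** — measured to the *start* of the first on-target
  fixation (≥250 ms within 1.5°), the literal reading of "first fixation
  reaching the target"; an anticipatory qualifying fixation is replaced by
  the next one, or the trial is dropped as missing.
* **Pursuit gain** — signed per-sample ratio of eye to target velocity
  along the motion axis, samples inside saccades/blinks excluded, ratios
  ≤ 0.5 dismissed.  Signed components mean anti-directed motion produces a
  negative ratio and is excluded by the floor, consistent with the floor's
  purpose.  Samples where |target velocity| < 1°/s (sinusoid turnarounds)
  are additionally excluded: the raw ratio there is unbounded and a single
  turnaround sample could otherwise dominate the trial mean.
* **Proportion of time pursuing** — retained-sample count × 4 ms divided by
  trial duration.  Note that even perfect tracking yields ≈0.94, because
  turnaround samples are excluded by construction.
* Missing values are carried with reasons and excluded listwise per metric
  in aggregation, so per-task missingness is visible in the summary table.

## Group statistics

Trial-level metrics are regressed on group with OLS point estimates and a
cluster-by-participant sandwich covariance with CR1 small-sample scaling
(G/(G−1) · (N−1)/(N−k), the Stata convention — the specific correction of
the original analyses is not recoverable, so CR1 is declared).  Age and
gender enter as covariates; target distance/verticality for pro-saccade
metrics and speed/axis for pursuit metrics as condition covariates.
Spearman correlations are pairwise-complete with midranked ties; cells
with fewer than 4 pairs are flagged.  No multiple-testing correction is
applied by default (matching the original analysis); a Benjamini–Hochberg
helper is provided.  Because real neuropsychology scores cannot be shipped,
`simulate_cognition_scores` draws synthetic scores from a latent severity
factor computed from each subject's own oculomotor profile, so the
correlation grid reproduces the published sign pattern in direction — its
magnitudes are a property of the generator, not of patients.

## Direction-state HMM and Fisher features

Displacement steps are built from consecutive valid samples; steps
straddling blinks are masked and split the trial into independent chains,
each restarted from π₁ (their log-likelihoods add).  U is the unit vector
from gaze to target, zeroed inside a 0.5° dead zone (on-target gaze carries
no directional information).  Before model fitting, 4 ms steps are
aggregated by summation into 20 ms steps (factor 5, exposed in
`EMConfig`): raw 4 ms displacements are dominated by tracker noise and
carry almost no directional signal.

The five sub-models share one geometry through fixed state-canonical
rotations: the displacement is rotated by the inverse of the state's
canonical angle, mapping intended motion onto +x (isometric,
parameter-free, identity for the rest state).  The target-alignment factor
is f(φ) = log(π/max(φ, ε)) with ε = 10⁻², where φ is the angle between U
and the state's canonical vector — logarithmic, strictly decreasing, zero
at φ = π; for the rest state and for U = 0 it takes the constant log 2
(its value at 90°, i.e. agnostic).  Both concretizations are declared
interpretations of the model's verbal description and are isolated in two
small functions.

Likelihood computations run in log-space with per-step max-shifting, so a
displacement dozens of SDs from every state (a saccade step under a
tracking-noise covariance) cannot underflow the forward recursion.  EM uses
closed-form M-steps with an eigenvalue floor of 10⁻⁸ on covariances,
initial means seeded at (median step length, 0) in every moving state's
rotated frame, three restarts keeping the best likelihood, and stops when
the per-iteration gain drops below 10⁻⁵.  The reference control is chosen
objectively as the control with the highest mean proportion-of-time-pursuing
(standing in for the original subjective choice of the best tracker), ties
broken by lowest subject id.

Fisher vectors are gradients of the forward log-likelihood at the fitted
parameters, computed from forward–backward expected sufficient statistics
(the Fisher identity).  The 55 coordinates are: 10 means, 15 unique
covariance elements (σ₁₁, σ₁₂, σ₂₂ per state, the off-diagonal gradient
doubled accordingly), and π₁ and the transition rows differentiated in
softmax coordinates — the chart is a choice, stated here, and used
identically by the finite-difference oracle.  The alignment factor is
parameter-free and contributes no gradient, consistent with scoring with
respect to the θ-dependent factors only.

## ARD classification and cross-validation

Features are summed over each subject's trials and divided element-wise by
the SD over individuals (constant coordinates dropped and recorded).  The
default recomputes the divisors on each training fold so no statistic of a
held-out subject touches training; a `paper_faithful_normalization` switch
restores one global normalization computed before splitting, as in the
original description.  The reference HMMs themselves are fitted once,
before cross-validation, to a single designated control.

The classifier is logistic regression with an independent zero-mean
Gaussian prior per weight.  Fitting alternates MAP weight estimation
(penalized logistic objective, L-BFGS) with MacKay evidence fixed-point
updates αᵢ ← (1 − αᵢΣᵢᵢ)/wᵢ², precisions capped at 10⁶ (effective
pruning); the intercept carries a fixed, effectively flat prior (10⁻⁶).
With separable training data the α-updates drift slowly rather than
converge, so the loop also stops at 50 outer iterations with a warning.
Predictions threshold σ(Zw) at 0.5 (argmax over two classes — the original
choice is unstated).

Leave-one-out is exhaustive; leave-two-out enumerates unordered pairs,
subsampled with the run seed above a ceiling (default 400 pairs);
leave-half-out uses seeded group-stratified half-splits (default 100;
stratification is adopted since the original partitioning is unstated).
Reported rates are per-class fractions of correct held-out predictions.

## Problem sizes and determinism

Default analyses use the study-sized cohort (21 + 36 subjects; 3, 40 and
12 trials per paradigm; 10 s at 250 Hz), which runs the full classification
pipeline in well under a minute and the complete analysis sequence in a few
minutes on one CPU.  Every stochastic component draws from seeds derived
from one master seed, and pipeline reruns with an identical configuration
are byte-identical (checksummed in the run manifest).

## Known limitations

* The generator's simulated group separation is cleaner than clinical
  reality; perfect cross-validated accuracy on synthetic cohorts is an
  upper bound, not a clinical claim.
* Square-wave-jerk counts depend on detecting both sub-2° saccades of a
  pair; at 250 Hz with realistic noise some pairs fall below the detector's
  resolution, deflating counts relative to their generating rate.
* The fixation-paradigm maximum fixation duration merges across blinks;
  parsers that split at blinks will report systematically shorter maxima.
* The HMM is fit to a single reference control per trial; subject-specific
  or mixed references are not implemented (they would change the meaning of
  the Fisher representation).
* Pro-saccade and fixation data are deliberately not fed to the classifier:
  those paradigms elicit one or zero gaze movements and carry little
  sequence information by design.
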