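# Methods

## The diagnostic model

The pipeline treats a subject-leg as a stack of 14 cycle waveforms — knee
flexion (degrees) and 13 knee-spanning muscle forces (newtons) — recorded
over one jogging gait cycle and summarized as follows.

**Preprocessing.** Muscle forces are nondimensionalized by body weight
(mass × 9.8 m/s²), every signal is resampled onto a 101-point grid
(0–100 % of the cycle, integer percent — the gait-analysis convention that
makes cycle percents addressable exactly), trials are averaged pointwise,
and each averaged signal is divided by its within-cycle maximum so that it
peaks at exactly 1. The order — nondimensionalize, resample, average,
normalize — is a design choice: averaging before normalization means the
normalization removes a single per-signal scale per subject, making the
pipeline invariant to multiplying a subject's raw forces by any positive
constant (a property the test suite enforces). Knee flexion skips
nondimensionalization but is amplitude-normalized like the muscles; if
hyperextension produces negative angles they are normalized by the signed
maximum and may remain below zero, with a warning. An all-zero signal
(inactive muscle) is passed through unchanged with a warning rather than
failing the subject.

**Characteristic points.** At each of the 101 percents a two-sided
two-sample *t*-test (pooled-variance Student by default; Welch by
configuration) compares ACLD and control values of each signal. Maximal
runs of consecutive points with *p* < α (α = 0.05) are located, and within
each run the point of minimal *p* — earliest index on ties, for
reproducibility — is kept. No multiple-testing correction is applied across
the 101 points; the run-minimum rule is the only filter, so the point set is
a descriptive screening device, not family-wise inference. Control subjects
contribute both legs as independent rows; the resulting within-person
dependence is a documented approximation, not corrected.

**PCA.** Covariance PCA (center, no rescaling — inputs are already on a
common [0, 1] scale): loadings are eigenvectors of the sample covariance
(divisor m − 1; the choice does not affect loadings or information-content
ratios), computed by SVD of the centered data matrix for stability and
verified in tests against an explicit covariance eigendecomposition. Each
loading column is flipped so its largest-absolute entry is positive, making
fitted models byte-reproducible (the SVD sign is otherwise arbitrary). New
samples are projected by centering with the stored training means and
multiplying by the stored loadings — never by refitting.

**Features.** Three phase-summary features (first PCA score of the
13 stance-phase muscle means, of the 13 swing-phase means, and of the
swing-phase knee-flexion trajectory) plus the first k composite-index
scores of the subjects × characteristic-points matrix. The stance/swing
boundary is a fixed cohort-level configuration, default 0.40 (typical foot
contact fraction in jogging), giving 41 stance and 60 swing grid points; it
is recorded in every output's metadata. Stance-phase knee flexion is
deliberately not a feature (its regression coefficient is not significant
and does not move the accuracy), and only the first score of each
phase-summary PCA is used (its information content dominates). The stance
and swing muscle means are compressed by two separate PCAs, matching the
reported model's two distinct coefficients, not one PCA of a concatenated
26-vector. Default k = 3 composite features (the reported optimal
condition); a 90 %-information-retention rule is available instead.

**Regression and classification.** With labels +1 (ACLD) / −1 (control),
ordinary least squares with intercept; standard errors from
σ̂²(XᵀX)⁻¹, coefficient t-tests with n − q − 1 degrees of freedom, an
overall F-test, R², and RMSE reported as the residual standard error
(n − q − 1 denominator, consistent with the reported fit). A score's sign is
the class; exactly 0 classifies as control — the conservative tie rule for a
surgical diagnosis, and a measure-zero event. Percentages are formatted to
one decimal, rounding half away from zero.

**Cross-validation.** Stratified k-fold (default 5) with a recorded seed.
`refit_all` (default) re-derives the characteristic points, all four PCAs
and the regression inside each training fold and projects held-out subjects
through the frozen fold pipeline; a test fixture verifies the fit phase
never touches test-fold rows. `reuse_features` computes features once on
the full sample and refits only the regression per fold — the optimistic
variant most waveform-classification studies implicitly use; keeping both
first-class makes the optimism measurable. Accuracy is reported from pooled
held-out confusion counts (which sum to the cohort size); per-fold
accuracies are also available.

**Recruitment solver.** The min/max criterion — minimize the largest
relative activation max fᵢ/Nᵢ subject to equilibrium C f = d and
0 ≤ fᵢ ≤ Nᵢ — is posed as a linear program in (f, ε) with ε ≤ 1 enforced
(forces may not exceed strength) and solved with the HiGHS backend. Because
the bare minimax LP leaves sub-maximal muscles underdetermined, an optional
refinement (default on) repeatedly freezes saturated muscles at their
forces, removes them from the ε constraints, and re-minimizes over the
remainder until all muscles are frozen or none saturate, yielding a unique
graded solution. Intended for small didactic systems, not for a full
lower-extremity model.

## The synthetic-cohort generator

The generator reproduces the *statistical* structure the analysis assumes:
25 ACLD legs (affected side only) vs 9 control volunteers × 2 legs
(18 records), 5 trials per leg, body masses drawn per person from
group-specific normals (82.04 ± 11.55 kg ACLD, 74.06 ± 4.73 kg control).
Waveforms are built from fixed per-signal templates (periodic Gaussian
bumps, peak 1, shaped after jogging electromyography: quadriceps and triceps
surae stance-dominant, hamstrings late-swing/terminal-stance, biphasic knee
flexion with the swing wave dominant) plus two smooth zero-mean periodic
random Fourier curves: a subject-leg offset (pointwise sd 0.08 of the
signal peak, 3 harmonics) and trial noise (sd 0.05, 8 harmonics). Smooth
curves rather than white noise give the pointwise t-tests realistic
autocorrelation. Group effects are Gaussian-bump (or plateau) mean shifts
added to ACLD legs in raw units *before* amplitude normalization, where
real group differences arise; `CohortSpec.effect_amplitude_for_d` converts a
target standardized difference on trial-averaged curves,
d·√(subject_sd² + trial_sd²/n_trials), into an amplitude. The noise levels
were fixed once at values giving ~8 % between-subject and ~5 % trial-level
waveform variability, within the range reported for time-normalized jogging
waveforms; the `paper_like_effects` preset places d ≈ 1.2 shifts in RF/VAS
(down), ST/SM/BFlh (up) around terminal stance and in swing-phase flexion
(down), following the qualitative pattern reported for ACLD jogging.

What the generator does **not** emulate: biomechanical coupling between
signals (each signal's variation is drawn independently, whereas real
muscle forces covary through the dynamics), event-based stance/swing timing
variation, asymmetric or skewed noise, meniscal-injury subgroups, and any
particular raw waveform realism beyond the template shapes. Passing tests
therefore demonstrate that the *procedure* recovers localized effects of a
given standardized size under physiological-looking smooth noise and is
calibrated when no effect exists — not that any particular clinical accuracy
is reproducible.

## Numerical choices

- Interpolation: linear (simplest defensible choice for monotone cycle
  registration); natural cubic spline behind a flag.
- Degenerate signals: within-cycle maximum ≤ 1e-12 skips normalization with
  a warning; numerically-zero within-group variance at a cycle point gives
  p = 1 when means agree (t = 0 convention) and p = 0 with a warning when
  they differ (identical subjects may differ by float rounding after scaling
  and renormalization, so the zero-variance test uses a 1e-9 relative
  tolerance).
- PCA on a constant matrix: identity loadings, zero eigenvalues, warning;
  the 90 %-retention rule returns k = 1 with a warning at zero variance.
- Rank-deficient regression designs raise an error naming the collinear
  columns (QR diagonal); k exceeding the available characteristic points is
  clipped with a warning, so no-signal training folds degrade gracefully to
  smaller (possibly intercept-only) models instead of failing.
- LP saturation tolerance 1e-7 (relative to strength), equilibrium residual
  tolerance 1e-8.

## Problem sizes in the validation suites

Monte-Carlo suites use the default study-size cohort (25 vs 18 legs,
5 trials) with 200 independent seeds for the characteristic-point recovery
and null-calibration checks and for the cross-validation null/power
comparison; oracle-equivalence suites use 100 random 6×4 matrices (PCA),
100 random 43×6 designs (OLS), and 50 random 2-dof, 3–5-muscle recruitment
problems (LP vs exhaustive vertex enumeration). Unit tests use smaller
cohorts (8–16 legs, 2–3 trials) where only plumbing is under test.

## Known limitations

- The characteristic-point selector performs no cluster-level or
  random-field inference; with 101 correlated tests per signal it will
  select spurious points at the nominal 5 % rate on null data. Downstream
  PCA + regression absorbs some of this, but the point set itself should
  not be read as a localization inference.
- Both control legs enter as independent samples; standard errors and CV
  accuracy are slightly optimistic in proportion to the within-person
  correlation.
- A linear model on ±1 labels is a classification heuristic: scores are not
  calibrated probabilities and no ROC analysis is provided.
- The recruitment solver handles equality-constrained box problems only; no
  ligament/contact forces, no polynomial recruitment criteria.
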