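# Methods

## Estimands and estimators

All risk-difference estimators target `E[Y(1)] − E[Y(0)]`, the marginal
effect of unemployment on the probability of poor self-rated health. The
propensity score `PS_i` is the fitted probability of being unemployed given
the baseline confounders, from a main-effects logistic model. Three
weighting estimators are implemented exactly as defined in
`causalrd.estimators`:

* the standard inverse-probability-weighting estimator, which divides by
  `n` and can in principle leave [−1, 1] when a participant carries an
  extreme weight (this is surfaced, not truncated — see *Numerical
  choices*);
* the augmented (normalised-weights) estimator, whose within-arm weight
  normalisation bounds it in [−1, 1];
* the doubly-robust estimator, which augments the weighted arms with
  predictions `m₀(Z_i)`, `m₁(Z_i)` from outcome models fit separately on
  the employed and unemployed strata, using the same covariates as the
  propensity model, and evaluated at every participant's covariates. The
  `1/n` normaliser is part of the estimator definition: without it the sum
  grows with `n` and cannot be a probability difference.

G-computation fits a single main-effects logistic outcome model including
exposure, then standardises: it averages predicted probabilities with
exposure forced to 1 and to 0 over the empirical covariate distribution.
Main effects are the default because the analysis this package supports
adjusts additively; an `exposure_interactions` option adds
exposure-by-covariate products, which with a single binary covariate
saturates the model and reduces G-computation to direct standardisation —
useful as an exact cross-check.

The logistic odds-ratio estimator reports `exp(β)` for exposure with a
profile-likelihood interval, the small-sample-appropriate choice for a
cohort with ~20% exposed.

## The in-house logistic fitter

Propensity models, stratum outcome models and odds-ratio models all go
through one Newton–Raphson (IRLS) fitter with fixed, platform-independent
criteria: convergence when the largest score component falls below 1e-8 or
the relative log-likelihood change falls below 1e-10, at most 50
iterations, with step-halving to keep the likelihood monotone. After
convergence, up to two polishing Newton steps push the score to machine
precision so that algebraic identities (saturated-model cell means, the
2×2 closed-form odds ratio) hold to ~1e-12.

The fitter is deliberately in-package rather than delegated: the bootstrap
needs *typed* failure signals. A constant response raises
`DegenerateResponseError`; diverging coefficients with fitted probabilities
pinned at 0/1 raise `SeparationError` naming the offending column; a
singular information matrix (collinear or constant columns, the usual
outcome of resampling a rare covariate level) raises `SingularError`; a
fitted propensity score at the floating-point boundary raises
`DivisionGuardError` when it reaches a weighting estimator. All derive from
`EstimationError`, the class the bootstrap skips and counts. No penalised
or bias-corrected variant is offered: small-sample instability is reported,
not patched.

Profile-likelihood bounds for a coefficient are the points where twice the
drop in profile log-likelihood (all other coefficients re-maximised via an
offset fit) equals the χ²(1) quantile, bracketed outward from the MLE in
Wald-standard-error steps and solved by Brent's method to better than 1e-6
on the coefficient scale. A side where the profile never drops far enough
is reported as an open bound (0 or +∞ on the odds-ratio scale).

## Bootstrap inference

Percentile bootstrap, unstratified simple random resampling of
participants, default 10,000 replicates (B). Unstratified resampling is a
deliberate choice: it allows replicates to lose most of an exposure group,
which is precisely the singularity mechanism the skip-and-count accounting
is designed to record. Quantiles use linear interpolation (type 7) for
cross-platform determinism. The bootstrap MSE is defined around the
full-data point estimate, `mean((θ*_b − θ̂)²)`, so it decomposes as
replicate variance plus squared deviation of the replicate mean from θ̂.

Failures are tracked per estimator: a doubly-robust failure on a replicate
discards only the doubly-robust value, not the G-computation or IPW values
from the same resample. When fewer than half the requested replicates
succeed, the result is flagged unreliable (an opt-in `strict` mode raises
instead); zero successes always raise. One set of resample indices can be
shared across estimators and across ledger models — within one run the
default — so that between-model deviations reflect adjustment sets rather
than resampling noise; fully independent resampling per model is available
by flag, which also answers whether MSEs should come from shared or
independent replicate sets (both are computable).

The replicate engine pre-encodes the design matrices once and warm-starts
each replicate's fits at the full-data coefficients; this changes nothing
statistically (the MLE does not depend on starting values) and roughly
halves runtime.

## Exposure modes and censoring

Unemployment around the mid-1990s baseline is measured three ways:
accumulated self-reported unemployment of at least 6 months over the last
three years; accumulated register-recorded unemployment of at least 182
days (the ceiling of 365/2 — the register stores day counts, the
definition is stated in months) over three calendar years; and a
currently-unemployed tick. "Employed" always requires at least 18 months
(1.5 years) of labour-market attachment — full-time work, part-time work of
20–39 hours, or a labour-market measure — with zero unemployment under the
mode's measure; everyone else is excluded with a machine-readable reason.
Months are treated as whole months. The censoring policy excludes
participants with any follow-up unemployment or under 18 months of
follow-up attachment; it only ever removes participants, never flips an
employed/unemployed call, and the same follow-up episode data serve all
three modes.

Current-status unemployment combined with censoring typically leaves very
few unemployed; the pipeline completes but suppresses interval estimates
below a configurable unemployed-count threshold (default 30) rather than
reporting unstable numbers. The threshold is explicit configuration, not a
hidden constant.

## The model ledger

Model 1 adjusts for all 11 confounders (alcohol intake, attachment
(AVAT), social integration (AVSI), BMI, cash margin, education, sex,
marital status, previous health, occupation, smoking); models 2–12 drop
each in turn; model 13 keeps the confounders significant in the full
logistic fit; models 14–17 drop each reduced-set member; models 18–24 add
back each excluded variable; a crude specification closes the grid.
Selection significance is judged at the *variable* level — a multi-level
variable is retained if any non-reference level's profile-likelihood
interval excludes an odds ratio of 1 at the 5% level — and variables enter
and leave atomically (all indicator columns together). Profile rather than
Wald intervals are used for selection, for consistency with the reported
interval method. Duplicate specifications (e.g. when the reduced set equals
the full set) are aliased and computed once.

## The synthetic cohort generator

The generator emulates the statistical structure of a northern-Swedish
school-leaver cohort analysed at n = 805: eleven categorical confounders
with realistic marginals (e.g. 23% poor previous health, 27% single, 42%
blue-collar, 6% obese), unemployment assigned by a logistic model on the
confounders, and the outcome by a logistic model on exposure and
confounders. Health selection is built in through the previous-health
coefficient in the exposure model (odds ratio 2.5). Confounders are drawn
through a Gaussian copula — independent by default, since only marginals
are reliably known; optional pairwise latent correlations add dependence
when wanted. Default effect sizes are calibration anchors chosen once: the
conditional exposure odds ratio is 1.9 and the previous-health odds ratio
4.0, magnitudes typical of fully adjusted fits on such cohorts; the two
intercepts were calibrated by Monte Carlo so that marginal unemployment
prevalence is ≈22% and poor-health prevalence ≈36%. Because the generating
models are known, `true_marginal_rd` evaluates the true estimand by
Monte-Carlo standardisation (default 10⁶ draws, with its standard error).

The labour-history generator produces the raw records the exposure module
consumes: retrospective 36-month status mixes, register day counts derived
from the self-reported months at 30.42 days/month (so the self-reported and
register modes classify identically at zero discordance), a current-status
tick, and follow-up episodes. A discordance rate injects register-only
spells — short unemployment periods a respondent would not recall but the
register records — which pushes the register mode toward more unemployed
and fewer cleanly employed participants, the direction observed when the
two sources disagree in practice.

What the generator does *not* emulate: attrition, measurement error in the
confounders, longitudinal health trajectories, and any joint confounder
dependence beyond the optional copula couplings. Tests passing on this
generator therefore demonstrate the correctness and calibration of the
estimation machinery under the assumed data-generating model, not
substantive conclusions about any real cohort. One known labelling
ambiguity: occupation's reference category is "low-to-medium white-collar",
whose share (41%) is taken from the medium–high white-collar row of the
marginal table; the remaining shares (17% high white-collar, 42%
blue-collar) complete the three-way split.

## Numerical choices and degenerate inputs

* Propensity scores are used as fitted, with no trimming or weight
  truncation; extreme weights surface through min/max PS diagnostics and,
  at the floating-point boundary, a typed division-guard error.
* Threshold codings: BMI boundaries 25 and 30 belong to the upper category
  ([25, 30) overweight, ≥30 obese); AVSI ≤ 13 and AVAT ≥ 10 fall in their
  reference groups (boundaries inclusive); an alcohol index of 140 is
  "high" (the low cut-off is strictly below 140).
* Complete-case analysis only: rows missing any study variable are dropped
  at load time and counted; no imputation.
* Bootstrap quantiles: type-7 linear interpolation; seeds: a single seed
  drives index generation, and scenario/acceptance runs derive sub-seeds
  from one master seed, all below 2³¹.
* Simulation sizes used by the validation suite — 1,000 random instances
  for formula oracles, 500 replicates at n = 2000 for the
  double-robustness study, 200 replicates at n = 5000 for parameter
  recovery, and 500 simulated cohorts with B = 500 for coverage — were
  chosen to give Monte-Carlo error comfortably below the tolerances they
  check while keeping the full suite in the minutes range on one CPU.

## Known limitations

* The doubly-robust estimator is genuinely unstable with very few exposed
  participants; the package reports the instability (effective replicate
  counts, reliability flags) instead of stabilising it.
* Profile-likelihood intervals require one nuisance refit per evaluation;
  the 24-model coefficient report is therefore the slowest path and is
  opt-in.
* The generator's truth is the truth of *its* model; misspecification
  scenarios cover omitted-confounder errors, not link misspecification or
  measurement error.
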