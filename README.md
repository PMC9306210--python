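# causalrd

Marginal risk-difference estimation for cohort studies of unemployment and
health, with a focus on how the *measurement* of unemployment, the choice of
estimator, and the confounder set move the estimated effect.

The package is aimed at epidemiologists and biostatisticians analysing a
binary "poor self-rated health" outcome against a binary labour-market
exposure in a moderately sized cohort (hundreds of participants), where the
key confounding pathway is **health selection**: people in poorer health are
more likely to become unemployed in the first place, so health measured
before the exposure window must be adjusted for.

## What it computes

All risk-difference estimators target the marginal causal contrast

```
RD = E[Y(1)] − E[Y(0)]
```

— the change in the probability of poor health if everyone were unemployed
versus everyone employed. With `PS_i = P(X_i = 1 | Z_i)` the propensity
score from a logistic model on confounders `Z`:

* **IPW (standard)** — `(1/n) Σ_i [ Y_i X_i / PS_i − Y_i (1−X_i) / (1−PS_i) ]`
* **IPW (augmented)** — the same weighted arms with weights normalised to
  sum to one within each arm, which bounds the estimate in [−1, 1]
* **Doubly robust** —
  `(1/n) Σ_i [ (Y_i X_i − (X_i−PS_i) m₁(Z_i)) / PS_i − (Y_i(1−X_i) + (X_i−PS_i) m₀(Z_i)) / (1−PS_i) ]`
  where `m₀`/`m₁` are outcome models fit on the employed/unemployed strata;
  consistent if *either* the propensity or the outcome models are correct
* **G-computation** — fit `logit P(Y=1) = α + βX + γᵀZ`, then average the
  predicted probabilities with `X` forced to 1 and to 0 for everyone
* **Logistic regression** — the conditional odds ratio `exp(β)` with a
  profile-likelihood confidence interval

Inference for the risk differences is by percentile bootstrap (10,000
replicates by default): each replicate resamples participants with
replacement and re-runs the whole chain (propensity fit, outcome fits,
estimator). Replicates where a fit degenerates — typically a resample with
too few unemployed — are skipped and counted, and the result carries an
effective replicate count, a bootstrap MSE (mean squared deviation of
replicates from the full-data estimate), and a reliability flag.

Around the estimators sit:

* **exposure modes** — derivation of employed/unemployed/excluded status
  from raw labour histories under three definitions (≥6 months self-reported
  unemployment over three years; ≥182 register-recorded unemployment days
  over three calendar years; currently-unemployed tick), plus a censoring
  policy that drops participants with any follow-up unemployment or under
  18 months of follow-up labour-market attachment;
* a **model ledger** — the 24-model confounder-sensitivity grid (full model,
  leave-one-out, significance-reduced model, and reduced ± each variable)
  with bootstrap resamples shared across models;
* a **synthetic cohort generator** with configurable marginals, a built-in
  health-selection mechanism, and Monte-Carlo evaluation of the true
  marginal risk difference, so every estimator can be validated against a
  known truth.

## Worked example

```python
import causalrd as c

config = c.GeneratorConfig(n=805, seed=1)
cohort = c.generate_cohort(config)

covariates = list(c.CONFOUNDER_ORDER)           # all 11 confounders
plan = c.BootstrapPlan(b=2000, seed=7)
results = c.bootstrap_many(cohort, covariates, c.RD_ESTIMATORS, plan)
for name, r in results.items():
    star = "*" if c.significance_flag((r.ci_low, r.ci_high)) else " "
    print(f"{name:18s} RD={r.point:6.3f}{star} "
          f"CI=({r.ci_low:.3f}, {r.ci_high:.3f}) MSE={r.mse:.4f} "
          f"B={r.effective_b}/{r.requested_b}")

orr = c.or_logistic(cohort, covariates)
print(f"logistic OR={orr.point:.2f} CI=({orr.ci_low:.2f}, {orr.ci_high:.2f})")

truth = c.true_marginal_rd(config, mc_n=1_000_000)
print(f"true marginal RD={truth.marginal_rd:.4f}")
```

prints

```
gcomp              RD= 0.124* CI=(0.045, 0.208) MSE=0.0018 B=2000/2000
ipw_standard       RD= 0.144* CI=(0.056, 0.236) MSE=0.0022 B=2000/2000
ipw_augmented      RD= 0.145* CI=(0.056, 0.237) MSE=0.0021 B=2000/2000
ipw_doubly_robust  RD= 0.146* CI=(0.060, 0.238) MSE=0.0021 B=2000/2000
logistic OR=1.82 CI=(1.26, 2.62)
true marginal RD=0.1364
```

Read: on this synthetic cohort (182 unemployed of 805), being unemployed
raises the probability of poor self-rated health twelve years later by
roughly 12–15 percentage points; the four estimators agree closely, all
intervals exclude 0 (starred), and the generating truth (0.136) sits inside
every interval. The same analysis is available from the shell:

```bash
causalrd simulate --n 805 --seed 1 --out-dir run/
causalrd estimate --cohort run/cohort.csv --estimators all --estimators or \
    --bootstrap 2000 --seed 7 --out run/estimates.csv
causalrd ledger --cohort run/cohort.csv --estimators gcomp --bootstrap 500 \
    --seed 7 --out run/ledger.csv
```

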