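# Methods

## The problem

A cluster-randomized trial (cRCT) estimates an intervention effect in
its own study population. Commissioners usually care about a different,
wider population — often observed only through routine cross-sectional
surveys, and often years after the trial ended. *Transportability*
methods estimate what the trial's effect would have been in that
external target population, under explicit assumptions, by re-weighting
the trial sample until it resembles the target.

This package implements that pipeline for the canonical school-based
setting: a two-arm school-randomized trial with a binary weekly-smoking
outcome, and serial survey waves of the same age band as the target
population at several calendar times.

## Estimand and identifying assumptions

The target quantity per survey year is the intention-to-treat odds
ratio for weekly smoking that would have been observed had the trial
been run in that year's target population. Identification requires:

1. **Conditional treatment exchangeability and treatment positivity**
   within the trial — both guaranteed by randomization.
2. **Conditional population exchangeability**: given the measured
   covariates, the treatment–outcome relation in the trial holds in the
   target. Untestable; it is a modelling assumption documented, not
   verified, by the pipeline.
3. **Population positivity**: every target covariate profile has trial
   counterparts in both arms. This *is* (partially) testable and the
   pipeline tests it (see Positivity below).

## Inverse odds of selection weighting

Trial and target records are harmonized to one categorical schema
(gender; age 12/13; ethnicity white/minority; smoking status
never / occasional-experimental-ex / weekly; age at first cigarette in
5 bands; lives with a smoker; lesson on smoking) and stacked with a
selection indicator S (1 = trial, 0 = target). A logistic selection
model P(S=1 | X) = expit(β₀ + Xβ) yields fitted probabilities pᵢ, and
each trial participant receives

    wᵢ = (1 − pᵢ) / pᵢ ,

the inverse odds of selection. Weighted this way the trial covariate
distribution matches the target's, so a weighted re-analysis of the
trial outcome estimates the transported effect.

**School effects in the selection model.** The natural impulse is a
school random intercept (students are clustered). But trial and target
schools are disjoint, so S is constant within every school and the
random intercept is *unidentified*: its ML variance diverges and the
intercepts absorb S entirely, leaving the covariate coefficients
meaningless. `fit_selection_model` detects school-constant S and drops
to a single-level fit with a logged warning; the random-intercept path
remains available for designs where S varies within clusters.

**Prediction mode.** Selection probabilities are marginal over any
school effect by default (Gauss–Hermite quadrature); a conditional mode
(per-school empirical-Bayes modes) exists for sensitivity analysis.
Weights are left unnormalized (an option renormalizes to mean 1), and
no truncation is applied by default; symmetric percentile truncation is
exposed as a diagnostic.

**Diagnostics.** The weight report carries the effective sample size
ESS = (Σw)²/Σw², weight quantiles and the fitted-probability range.
ESS/n is the honest price of the covariate shift.

## Positivity handling

Two failure modes are deliberately asymmetric:

* **Target-only level** — target students with no trial counterpart.
  This violates population positivity: the selection fit quasi-separates
  and the pipeline raises a `SeparationError` rather than report any
  estimate; the positivity report lists the offending cells.
* **Trial-only level** — trial students representing nobody in the
  target (e.g. an age-at-first-cigarette category a survey wave never
  recorded). Not a violation of the transport assumptions: in the MLE
  limit those students' weights tend to zero. The numerically stable
  version of that limit is to merge the level into the nearest adjacent
  supported level before fitting, which the pipeline does with a logged
  warning, recording every merge in the report.

## Outcome models

**Within-trial effect.** A school random-intercept logistic regression
of the follow-up outcome on arm, adjusting for the six school-level
stratification variables used at randomization (country, school type,
sex mix, language medium, year-group size band, free-school-meal band).
Stratification variables whose level is carried by fewer than two
schools are merged out with a warning. The arm coefficient is reported
as an OR with a Wald 95% CI (±1.96 SE on the log scale).

The engine is a hand-rolled Gauss–Hermite maximum-likelihood fit
(analytic gradients, L-BFGS-B, σ_u ≥ 0) because no installed Python
library provides frequentist logistic GLMM; it reproduces `lme4::glmer`
(nAGQ = 25) to ~5 decimals on fixtures, which is frozen into the test
suite. Exactly collinear design columns are aliased via pivoted QR, as
R does.

**Transported effect.** The same model fitted by *weighted
pseudo-likelihood*: weights enter as exponents inside each school's
likelihood integrand (the standard survey-weighted GLMM), so unit
weights reproduce the unweighted mixed fit exactly and integer weights
reproduce row replication exactly. Variance is the school-level
cluster-robust sandwich built from per-cluster scores (with a
J/(J−1) correction), which absorbs both the weighting and the residual
clustering and ignores the estimation noise in the weights (slightly
anti-conservative in principle; adequate in the recovery simulations).

**Weight scaling.** For a pseudo-likelihood mixed model the overall
scale of the weights is *not* innocuous, unlike a plain weighted GLM.
The default rescales weights to mean 1 inside the fit (Pfeffermann's
scaling method), which pins the choice down and makes the estimate
exactly invariant to rescaling the input weights by any constant;
`weight_scaling="none"` keeps raw frequency semantics (used by the
replication oracle).

**Precision metric.** The confidence interval ratio, upper 95% limit
over lower limit. For a Wald interval it is exp(2·1.96·SE): scale-free
and monotone in the standard error, so it cleanly expresses how
precision decays as the target drifts from the trial.

## Missing data

Questionnaire routing (2016/2021 waves) leaves about half the target
students without the lives-with-a-smoker answer; they are coded missing.

* **MAR diagnostic.** Per variable, a school random-intercept logistic
  regression of the missingness indicator on the observed covariates;
  null coefficients are consistent with MCAR, signal with MAR.
* **Imputation.** Default: chained equations with multinomial-logistic
  conditionals (every analysis variable is categorical), m = 20,
  10 cycles (1 cycle when a single variable is incomplete — its
  conditionals cannot change across cycles), each imputation fitting
  its conditionals on a bootstrap resample of the observed rows so
  parameter uncertainty propagates (approximate proper imputation).
  Alternative: a joint-normal model on the indicator-coded table with
  draws rounded to the nearest category. Trial and each survey wave
  are imputed separately; the selection model and weights are
  re-estimated within each completed dataset.
* **Pooling.** Rubin's rules: q̄, W (mean within variance), B (between
  variance), T = W + (1 + 1/m)B; degrees of freedom by Barnard–Rubin
  when a complete-data df is available, the classical large-sample
  formula otherwise; pooled CIs use the t quantile at that df. The
  Monte Carlo SE of q̄ is √(B/m); the m-sufficiency check flags
  mcse/√T > 0.1.

With zero missingness the pipeline takes the single complete-data path,
so MI output and complete-data output coincide exactly (asserted).

## The synthetic-data generator

The real trial and survey microdata are access-restricted, so a
generator emulates their shape; its defaults are the published study
conditions:

* Trial: 8756 students, 59 schools (30 intervention / 29 control; arm
  totals 4563 / 4193), stratified block randomization over the six
  cross-classified school strata with exact arm counts; school sizes
  multinomial with lognormal heterogeneity, summing exactly to the arm
  totals.
* Surveys: five waves sized 3958 / 3377 / 3145 / 4874 / 3587, with the
  published year-specific covariate marginals (weekly smoking falling
  3.6% → 0.2%, minority share rising 14.4% → 27.8%, lives-with-smoker
  falling 46.0% → 28.1%); survey school counts are set to ≈ n/35
  (not published; a typical cluster size). The 2016/2021 routing is
  simulated by dropping the lives-with-smoker answer for a random half.
* Covariate law: independent given the year, except that age at first
  cigarette is conditioned on smoking status (never-smokers always
  "never") to avoid logically impossible records. Where the printed
  marginals are mutually inconsistent by a few tenths of a percent the
  joint law reproduces smoking status exactly and age-at-first to the
  achievable accuracy.
* Outcome: random-intercept logistic with treatment log-OR ln(0.85),
  school SD σ_u = 0.35 (≈ ICC 0.035 on the latent scale, the typical
  range for school smoking outcomes; no ICC is published), covariate
  effects dominated by baseline smoking status (+1.6 / +3.5 log-odds),
  and an intercept solved numerically (quadrature over the random
  intercept, exact averaging over the covariate cells and both arms)
  so the marginal follow-up prevalence is exactly the 4.1% calibration
  target. Optional interaction terms put treatment-effect heterogeneity
  on chosen covariate levels; `true_transported_estimand` then obtains
  the per-year ground truth by brute-force large-sample simulation,
  while the homogeneous default is analytic (the conditional log-OR is
  ln(0.85) in every population).
* One global seed expands into named per-stage substreams, so adding a
  stage never perturbs earlier draws and every dataset is byte-stable.

What the generator does *not* emulate: within-school covariate
correlation (covariates are independent given the year), survey design
weights and school-level non-response, measurement error in
self-reports, and the intervention's diffusion mechanics. Passing tests
therefore show the estimator machinery is correct under the stated
model, not that the substantive published estimates are right.

## Numerical choices

* Gauss–Hermite: 15 nodes for model fits (25 for the lme4 cross-check
  and marginal predictions); intercept calibration uses 41 nodes and
  Brent root-finding to 1e-10.
* Optimizer: L-BFGS-B on (β, σ_u) with σ_u ∈ [0, 6]; plain-logit
  starting values; non-convergence raises, never silently regularizes.
* Separation: binary design columns whose support pins the outcome are
  detected up front and raised as `SeparationError`.
* Exact collinearity: aliased by pivoted QR (tolerance 1e-8); aliased
  columns carry zero coefficient at prediction time.
* Ties/degenerate inputs: single-cluster fits fix σ_u = 0 (plain
  logistic); a constant outcome within an arm is an error; empty target
  datasets are an error.

## Problem sizes in the tests

Simulation-based tests choose sizes that make their Monte Carlo
tolerances meaningful: marginal-convergence checks at n = 1e5; transport
recovery through the full pipeline at n_trial = 50 000 (200 schools)
with a strong designed covariate shift (ESS/n ≈ 0.25), asserted within
3 SEs of ln(0.85); precision-ordering at 100 replicates of a
2000-student trial across three increasing shift strengths; coverage at
60 replicates. The acceptance script averages 50 replicate default
trials for the calibration targets.

## Known limitations

* The selection model is single-level whenever trial and target schools
  are disjoint (see above); between-school selection heterogeneity is
  then absorbed into the covariates.
* The sandwich variance ignores weight-estimation noise; in the
  recovery simulations the empirical SD exceeded the mean sandwich SE
  by ~20% under strong shift.
* Chained-equations imputation uses bootstrap parameter draws rather
  than exact posterior draws; with m = 20 and the missingness rates
  simulated here the Monte Carlo error check stays far below its 0.1
  threshold.
* Doubly robust / augmented transport estimators and risk-difference
  summaries are documented extensions, not implemented.
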