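# Methods

## Estimands and model

The analysis targets the causal effect of resting heart rate (bpm) on
the log hazard of incident atrial fibrillation, allowed to differ
across three heart-rate strata. Within stratum *j* the estimand is a
local per-bpm slope β₃ⱼ; a U-shaped causal relationship would appear
as a sign change across strata (negative below 65 bpm, positive above
75 bpm).

Identification uses a weighted heart-rate polygenic risk score as the
instrument, under the usual MR assumptions: the score is (i) associated
with heart rate, (ii) independent of confounders of heart rate and AF
(genotypes fixed at conception), and (iii) affects AF only through
heart rate (no horizontal pleiotropy). Assumption (iii) is probed by
regressing AF on the score *adjusted for heart rate* — any residual
association suggests an outcome path bypassing the exposure — with the
three per-stratum p-values combined by Fisher's method.

### Stratification without conditioning on a collider

Stratifying on raw heart rate would condition on a common child of the
instrument and of confounders, opening a spurious instrument–outcome
path inside each stratum. The pipeline therefore stratifies on the
IV-free heart rate

    ivfree_hr = hr − ŝ·(prs − mean(prs)),

where ŝ is the cohort's own fitted first-stage slope (each cohort has
its own heart-rate scale, and all first-stage regressions are run per
cohort). The centred form preserves the cohort mean heart rate so the
fixed 65/75 bpm cutpoints remain meaningful on the observed scale.
Boundaries are half-open on the right: low < 65 ≤ mid < 75 ≤ high.
A pooled-tertile mode (`stratum_mode: tertiles`) is available; the
fixed cutpoints are the default and are configuration values, not
data-driven quantities. The first stage is covariate-adjusted by
default (`first_stage_adjusted`), with an unadjusted option.

A consequence of using an *estimated* ŝ, worth knowing when reading
per-stratum first-stage output: conditional on a stratum of
`hr − ŝ·prs`, the regression of heart rate on the score has
expectation ŝ itself, not the true slope, because
cov(hr, prs | stratum) = ŝ·var(prs). Under a truly null instrument the
per-stratum first-stage z-statistics are therefore inflated relative
to zero (they sit near the full-cohort ŝ, whose estimation error does
not shrink relative to the smaller within-stratum SE). This does not
bias the ratio estimator under a usable (non-null) instrument, where
the relative error of ŝ is small; the test suite asserts the correct
null behaviour (per-stratum slopes centred on ŝ, ŝ centred on zero).

### Stage models

* β₁ (per stratum): ordinary least squares of heart rate on the score
  plus covariates (age, sex, genetic PCs, center where present; sex
  coded female = 0, male = 1 — any consistent coding moves only the sex
  coefficient).
* β₂ (per stratum): Cox proportional hazards of incident AF on the
  score plus the same covariates, Efron tie handling, SE from the
  observed information. Cohorts without follow-up times are fitted by
  maximum-likelihood logistic regression and their log odds ratio is
  pooled as an approximation of the log hazard ratio (reasonable for a
  cumulative incidence around 10%); a warning is logged whenever
  scales are mixed.
* Pleiotropy model (per stratum): as β₂ with heart rate added to the
  covariates.
* Observational U-shape (full cohort): Cox (or logistic) on
  `hr − 70` and `(hr − 70)²` plus covariates. Centring at a common
  70 bpm improves conditioning and keeps coefficients poolable across
  cohorts; the quadratic coefficient is invariant to the centre and the
  nadir is recovered as `70 − β_lin/(2·β_quad)` when β_quad > 0
  (undefined otherwise, by design rather than error).

All Wald p-values use the two-sided normal convention
`p = 2(1 − Φ(|β/se|))`, including for OLS, so per-cohort and pooled
estimates share one convention.

### Pooling and the ratio

Fixed-effect inverse-variance pooling (weights 1/se²) feeds the ratio
estimator; DerSimonian–Laird random effects (moment τ²) is computed and
reported alongside, with Q and I² in both cases. Making fixed-effect
primary reflects that the per-stratum causal
estimate should weight cohorts by information, with heterogeneity
surfaced rather than absorbed. With a single cohort the estimate passes
through (Q, I², τ² undefined; reported as 0 internally and NA in
tables).

The per-stratum causal estimate is β₃ = β₂/β₁ with first-order
delta-method SE assuming independent stages,

    se₃² = se₂²/β₁² + β₂²·se₁²/β₁⁴.

Both stages come from the same samples, so the independence assumption
is a (standard) approximation; the Monte-Carlo check in the test suite
validates the formula itself to within 5% at the stage-uncertainty
levels this design produces. A first-stage F = (β₁/se₁)² below 10
attaches a weak-instrument flag; an exactly-zero β₁ is an error.
Hazard ratios are reported per 1 bpm and per 5 bpm
(`exp(5·β₃)`, so the per-5 value is exactly the fifth power of the
per-1 value), with 95% CIs using the 1.96 normal quantile.
Significance uses the printed three-test Bonferroni threshold 0.017
(strict inequality); for other test counts, 0.05/n exactly.

A note on the published inputs used in the worked examples: the
consortium's results list the mid-stratum pleiotropy p as 0.082 in the
main text and 0.111 in the supplementary caption. The package carries
the main-text values (0.052, 0.082, 0.778), which reproduce the
published Fisher combination p = 0.076; the discrepancy is documented
here, not resolved.

## Synthetic consortium generator

One global seed fans out (via `numpy.random.SeedSequence.spawn`) to a
shared-variant substream plus one substream per cohort, so adding a
cohort never perturbs existing cohorts and identical configurations are
byte-identical.

Per cohort of size n (defaults mirror the consortium scale: eight
cohorts of 2,000–9,000, heart-rate means 63–73 bpm, age means 49–75):

* dosages: `Binomial(2, f_i)` with shared frequencies
  `f_i ~ U(0.1, 0.9)`; weights `w_i ~ N(0, 0.25²)` bpm/allele, drawn
  once and shared; about half the variants are stored as doses of the
  other allele so alignment is exercised.
* heart rate: `hr = mean_c + γ·(prs − E[prs]) + a·U + ε`, with γ set
  from the theoretical PRS variance so the score explains `prs_r2`
  (default 0.02) of the heart-rate variance (SD 11 bpm), `U ~ N(0,1)`
  an unmeasured confounder (a = 3 bpm), and ε filling the remaining
  variance (infeasible combinations raise a configuration error).
* hazard: `λ = λ₀·exp(F(hr*) + b·U + 0.05·(age−60) + 0.4·male)` with
  λ₀ = 0.01/yr, b = 0.3, and F the *integrated* piecewise-linear causal
  function with knots at 65/75 — so the per-stratum slopes are exact
  recovery targets. Crucially F acts on `hr* = hr − a·U`, the
  genetic-plus-noise component: the score is a valid instrument by
  construction while U confounds the observed association.
* follow-up: event times exponential, censoring `U(0, 20)` years;
  the designated binary-only cohort keeps the event indicator and
  drops the time. Under the default configuration the pooled event
  fraction lands at 12–13%, inside the 5–20% range of the cohort
  descriptives.
* default causal slopes are the published per-stratum point estimates,
  ln(0.82)/5 ≈ −0.0397 (low and mid) and ln(1.16)/5 ≈ +0.0297 (high).

What the generator does **not** emulate: linkage disequilibrium,
population stratification, genotyping error, age-dependent AF hazards
beyond a linear log-hazard term, cohort-specific censoring patterns,
or medication effects on heart rate. Passing tests therefore show that
the estimators are correct under the design's own assumptions, not
that those assumptions hold in any real cohort.

## Numerical choices

* Cox fits: lifelines' Newton solver tightened to a step precision of
  1e-9 (max 500 steps) so small-sample fits agree with brute-force
  partial-likelihood maximisation to 1e-4; monotone likelihoods and
  other non-convergence raise errors rather than returning NA.
* Logistic fits: statsmodels Newton ML; perfect separation (detected
  by non-convergence or runaway coefficients) raises an error.
* Rank-deficient designs raise an error naming the offending columns;
  strata with zero events are excluded from pooling with a logged
  warning (the partial likelihood is undefined there).
* Missing doses: explicit `NA` sentinel; mean-dose imputation by
  default, `drop_variant` as an option. Missing phenotype rows and
  prevalent-AF participants are excluded with per-cohort counts
  logged, so input n = analysed n + excluded n is always auditable.
* An exact linear first stage (zero residual) reports se = 0 and a
  degenerate p of 0 or 1 rather than NaN.

## Problem sizes used by the validation suites

The simulation suites use sizes chosen to make each property sharp at
desk scale: parameter recovery runs the generator at a pooled
n = 200,000 (4 × 50,000) with a globally linear slope of −0.008/bpm so
the low-stratum estimand is unambiguous; the type-I-error study uses
1000 single-cohort replicates of n = 1,500 (~150 events each, ~50 per
stratum), the smallest size at which the Wald/ratio asymptotics are
trustworthy; the collider-avoidance demonstration uses n = 30,000 with
the confounder strengthened (a = 6, b = 0.8) and r² = 0.05 so the bias
from raw-heart-rate stratification is visible against sampling noise.

## Known limitations

* The delta-method SE ignores the covariance between the two stage
  estimates (same samples); with a strong first stage the effect is
  second-order.
* The log-odds-for-log-hazard approximation for binary-only cohorts
  is not converted or reweighted, mirroring the consortium analysis.
* Strata are formed on IV-free heart rate but the generator's causal
  function acts on the causal component of heart rate, so participants
  near cutpoints can be locally misassigned; with smooth piecewise
  slopes this attenuates, which is why recovery tests use a globally
  linear causal function.
* No LD pruning, weight re-estimation, Egger/median MR variants, or
  doubly-ranked stratification; the fixed-cutpoint residual
  stratification is the implemented design.
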