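# Methods

This note documents the statistical procedures, the synthetic data
generating process, and the numerical/design choices behind them.

## Exposure model

The comprehensive smoking index treats smoking as a dose that
accumulates during the smoking window and decays exponentially after
cessation, with half-life τ = 25 y; a lag of δ = 0.5 y immediately before
the index date is excluded on the grounds that very recent exposure has
not yet had time to act on the outcome. Intensity enters as
ln(int + 1), so CSI is 0 exactly for never smokers and saturates at
ln(int + 1) for very long, current exposure. Three analytic properties
are enforced by tests: the saturation limit, exact halving when time
since cessation grows by one half-life (for tsc ≥ δ), and monotonicity
in each dimension.

Current smokers ("smoked within the year before enrollment") are scored
with tsc = 0: their exact cessation offset inside the last year is
unobserved, and δ already discounts the most recent half-year. Ever
smoking requires > 1 year of smoking; shorter exposure counts as never.

**Sensitivity lag.** To limit reverse causation (early disease changing
smoking behaviour), all smoking variables can be recomputed as of
L years before the interview (L = 3 by default in the sensitivity
re-run). This is implemented as window truncation: duration loses
`max(0, L − tsc)` years, cessation is treated as occurring at
`max(tsc, L)`, and histories whose truncated duration no longer exceeds
one year are reclassified never for the lagged run. An independent
annual-grid oracle (enumerate smoked years, drop the last L, recount)
verifies the arithmetic in the tests.

**Codings.** Tertile cutpoints among ever smokers use
linear-interpolation empirical quantiles (`numpy.quantile` default);
study-specific cutpoints are data-dependent by design, so the quantile
rule only needs to be fixed and documented. Intervals are half-open
(a, b]: a value equal to a cutpoint falls in the lower tertile. The
fixed intensity bins 1–9 / 10–19 / ≥ 20 cig/day use inclusive lower
bounds so that 19 → "10–19" and 20 → "≥ 20". Per-category medians of the
underlying continuous variable (0 for never smokers) supply the
continuous score for the trend test.

## MetS classification

The classifier is three-valued. Each of the five component criteria is
positive, negative or missing; a criterion is missing only when every
datum that could decide it is missing (Kleene logic — e.g. the
blood-pressure criterion with one observed pressure below its cut and
the other missing is undecided, because the unseen pressure could still
exceed its cut; a reported medication decides glucose or blood pressure
regardless of the measurement). MetS status is positive when ≥ 3
criteria are positive, negative when even counting all missing criteria
as positive cannot reach 3, and **indeterminate** otherwise. This rule
is provably the same as enumerating all completions of the missing
criteria and checking whether they agree, and the test suite verifies
that equivalence exhaustively over all 3⁵ flag patterns. Indeterminate
("equivocal") records are excluded first in the eligibility filter.

TG/HDL medication is not part of the shipped CDS-2013 preset because
drug treatment is specified only for glucose and blood pressure;
alternative criteria (e.g. the 2009 Joint Interim Statement) can be
supplied as a `CriteriaSet` but no validated preset is shipped for them
since the exact alternative thresholds used alongside CDS-2013 in this
design are not published.

## Association models

Odds ratios come from maximum-likelihood Bernoulli-logit fits (Newton
iterations, coefficient tolerance 1e-8, ≤ 100 iterations, one BFGS
continuation pass if Newton oscillates; covariance is the inverse
observed information; fitting is delegated to statsmodels behind the
module surface). The CI multiplier is fixed at 1.96 (Wald 95%).
Rank-deficient designs and (quasi-)complete separation raise explicit
diagnostics naming the offending terms rather than returning unstable
estimates; separation is reported, not repaired (no Firth correction).

Age and BMI enter continuously; categorical covariates are dummy-coded
against their most frequent level. Stepwise covariate selection is
classical forward selection with backward elimination on
likelihood-ratio p-values (entry p < 0.05, removal p > 0.10; the
LR flavour is chosen over Wald as the standard for this idiom and the
more stable at small cell counts). p_in < p_out guarantees termination.

The trend test replaces the exposure categories by each participant's
category median and reports the Wald p of that single continuous term.
Under the null its type-I error is verified to sit within a 3-SE
binomial band of 5% over 1000 replicates at n = 2000.

## Interaction

Multiplicative interaction: one pooled model with exposure-category ×
modifier product terms; the reported p is the joint Wald chi-square over
all product terms (df = number of non-reference categories); per-term
p-values are available in verbose output. Stratified models drop the
categorical covariate the modifier dichotomises (exactly collinear with
the modifier) and any covariate level that carries only cases or only
non-cases within a stratum (such levels quasi-separate the fit).

Additive interaction: RERI from a single model with indicators for
exposed-only, modifier-only and both (smoking dichotomised never/ever),
RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1. The 95% CI uses the delta method on the
three log-OR coefficients with gradient (−OR₁₀, −OR₀₁, OR₁₁) and their
estimated covariance (Hosmer–Lemeshow construction); a nonparametric
bootstrap percentile CI is available behind a flag as a cross-check.
With odds ratios, RERI approximates additivity of risk ratios only when
the outcome is reasonably rare in all four cells — a caveat for the
older, high-prevalence cohort. RERI is symmetric in which factor is
labelled exposure versus modifier.

## Missing data

Two mechanisms are implemented, matching the two cohort protocols:
median replacement (missing daily intensity among ever smokers set to
the observed ever-smoker median) and chained-equation multiple
imputation. The MICE sampler initialises missing entries from observed
marginals and then, per sweep and per incomplete variable, fits the
conditional model (linear, logistic or multinomial on all other
columns) and draws imputations from the predictive distribution with
parameter uncertainty included (normal posterior draw of coefficients;
scaled inverse-χ² draw of the residual variance for linear models).
Defaults: m = 5 chains, 10 sweeps — a minimal proper-imputation
construction; predictive mean matching is deliberately out of scope.
The analysis outcome (MetS) is used as a predictor in covariate
imputation but is never itself imputed (equivocal records are excluded
upstream). Estimates are pooled by Rubin's rules
(T = W + (1 + 1/m)·B) with a Barnard–Rubin t reference; under MI the
interaction Wald p is reported as the median across imputed datasets
(proper chi-square pooling is not implemented).

## Synthetic cohorts

The generator emulates the two survey samples' structure: a
`discovery_like` profile (ages ≥ 60, urban; age = 60 + Gamma(1.6, 5.7),
~63% below 70; male fraction 0.465; ever-smoking prevalence 20% in men,
1.1% in women, 94% of them current) and a `replication_like` profile
(ages ≥ 18 with mean ≈ 50; nine provinces, urban/rural; ever smoking
58%/5% by sex). Daily intensity is a discretised log-normal clipped to
[1, 60] with a negative age trend (older cohorts smoked less — the
source surveys report mean CSI 0.18 below age 70 vs 0.13 at 70+), start
age ≈ N(21, 4), and former smokers quit ≥ 1 y before index with a gamma
cessation-time; all histories satisfy the exposure invariants by
construction.

Smoking acts on the five MetS **components**, not on MetS directly: each
criterion flag is drawn from a logistic model on age, sex, BMI, the true
CSI and one shared standard-normal latent factor (loading 0.9) that
induces the observed clustering of components. The CSI slopes are
strongest on blood pressure and HDL, mirroring the component-level
pattern seen in the source analysis, and are multiplied by 2.4 below age
70 (age modification). The MetS-level odds ratio is therefore an
*emergent* quantity; under the default discovery conditions the induced
top-tertile adjusted OR, measured by simulating 10⁶ participants and
fitting the same adjusted model (self-oracle), is ≈ 2.0, with stratum
ORs ≈ 2.5 (< 70 y) and ≈ 1.5 (≥ 70 y).

Per-component intercepts are the logits of the target component rates
plus one global shift shared by all components, calibrated by Brent
root-finding so that the expected ≥ 3-component co-occurrence rate
(computed exactly as a Poisson-binomial tail, hence smooth) matches the
target MetS prevalence (23.3% discovery, 18.2% replication). The
calibration sample uses a fixed internal stream, making the shift a
deterministic function of the model parameters: cohorts replicated
under different seeds share one data-generating process.

Measurements are then materialised consistently with the drawn flags
(e.g. waist above/below the sex-specific cut; medicated-but-controlled
blood pressure and glucose occur among flag-positives), so re-deriving
the flags from the measurement columns reproduces the drawn flags
exactly. Equivocal records are produced by masking component
measurements until the classification is indeterminate; medication-
decided components are never masked.

Missingness injection is record-level at a configurable rate (7.1%
default) with three mechanisms: MCAR; MAR(age, sex) (logistic in
standardised age and sex — elderly underreporting); and MAR(outcome)
(logistic in observed smoking status, observed MetS and their product —
exam-item avoidance concentrated in affected smokers). The last exists
because covariate-only selection leaves the complete-case logistic OR
essentially consistent; selection tied jointly to exposure and outcome
is the textbook situation where complete-case analysis fails and
multiple imputation, which retains those records, repairs it. The MI
validation uses that mechanism.

**What the generator does not emulate:** survey design (clusters,
weights, households), longitudinal follow-up, measurement error in
self-reported smoking, secular cohort effects beyond the intensity age
trend, and real-world covariate–exposure dependence beyond age/sex.
Passing recovery tests therefore demonstrates the pipeline's
correctness under a known DGP, not the validity of the source surveys'
substantive estimates.

## Problem sizes used in validation

Chosen to give stable Monte-Carlo assertions: self-oracle at n = 10⁶;
parameter recovery over 200 replicates of n = 15,000 (CI coverage
≥ 93%, younger-stratum OR above older-stratum OR in ≥ 90%); MI versus
complete-case over 500 replicates of n = 3,000 against a full-data
estimand at n = 300,000; null calibration of the trend and interaction
tests over 1000 replicates of n = 2,000. The acceptance script uses a
scaled-down oracle (n = 250,000) and 60 coverage replicates.

## Known limitations

Cross-sectional logic throughout (no incidence, no survival); RERI on
the odds scale in a high-prevalence stratum overstates additivity
departures; the stepwise procedure inherits the usual post-selection
inference caveats (selection and estimation reuse the same data); the
MI multinomial conditional uses a BFGS fit that can be slow on many
levels; significance is fixed at two-tailed 0.05 with no multiplicity
correction, mirroring the source protocol (a Bonferroni switch exists
but is off by default).
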