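# Methods

This note documents the statistical model behind `trialcea`, the defaults
and their units, what the synthetic generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Setting

A two-arm randomised trial of a wound-edge protection device (WEPD,
£15/unit) against standard care in laparotomy patients, evaluated from a
health-service perspective over a 30-day post-operative horizon. With a
horizon this short no discounting is applied. The unit of analysis is the
patient; the trial's published arm-level summaries (369 device / 366
standard-care patients) calibrate the default synthetic profile.

## Costing

Per-patient cost = device cost (intervention arm only) + inpatient block +
primary-care block. The inpatient block prices general-ward, ITU and HDU
days separately; ward days are `inpatient_days − itu_days − hdu_days`,
floored at zero (the source prices a general-ward day separately but never
states this decomposition; flooring is logged per patient). The
primary-care block prices GP, practice-nurse, district-nurse and
outpatient visits and adds an already-priced medication spend (a per-drug
formulary is out of scope; an absent medication field counts as £0, since
it carries no missingness in the calibration data). Unit costs are 2011 £
values; ITU/HDU day prices originate from 2007/08 reference costs and the
`inflate_unit_cost` operation restates prices across years by the ratio of
a pay-and-price index (the bundled index file is a labelled synthetic
stand-in with representative values — substitute the published series for
real costing work).

Missing quantities propagate null components and null totals; filling
happens upstream (imputation) or rows are dropped (complete case).
Arm summaries report the mean and two standard errors: distribution-free
SD/√n (default) and a gamma-MLE-based SE, mean/√(n·α̂), reflecting the
usual gamma assumption for right-skewed costs (falls back to SD/√n when
non-positive values are present). All arithmetic is full precision;
whole-£ rounding (half away from zero) is applied only in reports.

## Utilities and QALYs

EQ-5D-3L profiles (five dimensions × three levels) are scored with the UK
time-trade-off value set as a pure lookup-sum: 1 minus a constant 0.081
for any dysfunction, minus per-dimension level-2/3 decrements, minus 0.269
if any dimension is at level 3; range [−0.594, 1]. The tariff ships as a
CSV and is swappable.

QALY over 30 days = trapezoidal area under the utility line between the
baseline and 30-day assessments, divided by 365.25 days/year (both the
between-assessment shape and the year length are conventions, exposed as
options). A death on day d accrues utility declining linearly from
baseline to zero at day d and zero afterwards; last-value-carried-forward
is available as an alternative. The interim 5–7-day assessment never
enters the QALY; it serves as an imputation predictor only. Incremental
QALYs are baseline-adjusted by OLS of QALY on the arm indicator and
mean-centred baseline utility, the standard correction for chance baseline
imbalance; adjusted arm means are predictions at the grand-mean baseline.

Note: the published arm QALY means (≈0.0213) are not derivable from the
published baseline/30-day EQ-5D means under any standard area-under-curve
convention (the trapezoid gives ≈0.059 for utilities of 0.75 and 0.68).
The accrual convention behind that figure is therefore unknowable from the
printed record; this package implements the standard trapezoid and treats
the printed *increment* (−0.00002) and summary-calibrated analyses as the
reproduction surfaces.

## Missing data

Chained equations: each incomplete variable is regressed on the others
(targets kept filled along the chain plus complete covariates, including
the arm indicator and the 5–7-day utility), cycled for `n_iterations`
sweeps, repeated m times. Continuous and count targets use Bayesian
linear regression with predictive mean matching (donor pool k): the
imputed value is an observed value, so utilities stay in the index range
and counts stay non-negative. Binary targets use a logistic draw with
parameter uncertainty, degrading to PMM under separation. Defaults
m = 20, `n_iterations` = 10, k = 5 — contemporary practice; the source
reports none of these. Imputation separately by arm is off by default,
available as a flag. Downstream estimates are pooled by Rubin's rules
(total variance = within + (1 + 1/m)·between) with Barnard–Rubin
small-sample degrees of freedom when the complete-data df is supplied.

## Uncertainty

Non-parametric bootstrap at the patient level, stratified by arm so arm
sizes are preserved (unstratified resampling is available), B = 1,000 by
default. Intervals are BCa: z₀ from the fraction of replicates below the
point estimate (ties count half), acceleration from the jackknife
skewness formula; endpoints are linear-interpolated quantiles at the
adjusted levels, so with z₀ = a = 0 the interval equals the percentile
interval exactly. Degenerate replicate clouds collapse to a point
interval; replicates on which a statistic is undefined are redrawn and
counted. For the mean-difference statistic both the resampling and the
jackknife are closed-form and vectorised.

Bootstrap–imputation nesting: imputation first, then B replicates within
each completed dataset; the point estimate is the mean of per-dataset
increments, the replicate clouds are pooled, z₀ comes from the pooled
cloud and the acceleration is the mean of the per-dataset jackknife
accelerations. The source does not state its nesting; this order keeps
the imputation uncertainty visible in the cloud at m× the replicate
budget.

ICERs are reported only in the trade-off quadrants; dominance labels
otherwise (a ratio of increments with opposite signs is sign-ambiguous
and carries no decision information). CEACs: at each λ on a £0–£50,000
grid (£100 steps, covering the conventional £20,000–£30,000 decision
range), p(cost-effective) = fraction of replicates with positive
incremental net monetary benefit λ·ΔE_b − ΔC_b, exact ties split half —
so the two alternatives' curves sum to one at every grid point.

## Regression adjustment

Pre-specified covariates: arm, baseline utility (QALY model only), stoma
plan, viscus plan, elective/emergency surgery, age, BMI, diabetes, current
smoking, SSI. Identity link throughout so the arm coefficient is an
additive £ or QALY increment; gamma family for costs, normal for QALYs
(the normal-identity fit coincides with OLS exactly). Continuous
covariates are mean-centred, making the arm coefficient an at-the-means
increment. Non-positive costs under the gamma family are shifted to £0.01
(logged; a drop policy is available) — rare by construction since every
intervention-arm patient carries the £15 device.

The identity-link gamma likelihood is awkward: unconstrained Fisher
scoring can propose negative means and plain IRLS oscillates near the
optimum. The fitter is Fisher scoring with step-halving (a step is halved
until the proposed means are positive and the deviance does not increase),
started from a flat mean; the statsmodels fit is used to polish and
summarise when it holds the optimum, otherwise Wald summaries come from
the analytic Pearson-scale covariance φ̂(XᵀWX)⁻¹. CIs for adjusted
increments are Wald by default; in the multiply-imputed scenario the arm
coefficient is Rubin-pooled across completed datasets.

## Scenario matrix

{base case (multiply imputed), complete case} × {unadjusted, adjusted}.
"Complete case" is operationalised as: no missing resource-use field, a
computable QALY (baseline utility plus either the 30-day utility or a
death), and no missing adjustment covariate; the same predicate feeds
both complete-case cells. A configurable floor (default 50 patients)
aborts the complete-case cells with a log entry instead of producing
unstable estimates.

## The synthetic generator

The generator emulates the *structure* of the source trial, calibrated to
its printed summaries; it is a study-conditions simulator, not a patient
simulator. Defaults (per arm where applicable):

- **arms**: 369 / 366 patients; 30-day death probability 8/369 and
  12/366, death day uniform on 0–30;
- **length of stay**: lognormal matched to mean (SD) 12.55 (15.46) and
  11.56 (11.68) days, rounded to half days, minimum half a day;
- **ITU/HDU days and visit counts**: zero-inflated negative binomial,
  moment-matched to the printed mean/SD given a structural-zero
  probability (0.80 ITU, 0.60 HDU, 0.50 GP, 0.85 practice nurse, 0.70
  district nurse, 0.60 outpatient — chosen once to respect the printed
  zero medians and keep the NB feasible; a zero-inflated Poisson fallback
  covers infeasible corners). Critical-care days are rank-coupled to
  total stay (a within-arm permutation, so marginals are exact) and
  capped at the stay length; the cap costs ITU/HDU means ≈2% downward
  bias and is the price of the stay-consistency invariant;
- **EQ-5D**: per-timepoint latent Gaussians (censored-moment-solved so
  the censored mean/SD hit 0.751/0.307-style targets), correlated 0.5
  across baseline / 5–7 d / 30 d, snapped to the nearest of the 243
  achievable 3L profiles — the scoring module is genuinely exercised.
  The interim assessment's mean 0.60 (SD 0.30) is a package choice
  (patients are worst shortly after surgery); the source prints no
  interim summary;
- **missingness**: MCAR at the printed per-field marginals; the 30-day
  EQ-5D marginal (51/369, 53/366 ≈ 14%) *includes* deaths, and the
  survivor non-response rate is derived as (p − p_death)/(1 − p_death) so
  the overall marginal is matched by construction. A MAR-on-SSI option
  exists to stress-test the imputation. Only marginals are matched: the
  joint structure (the source's 20.4% any-incomplete, complete-case
  n = 532) is unknowable from the printed record; independent marginals
  land the complete-case fraction at ≈73–75% versus the published 72.4%;
- **covariates**: age N(62, 14) years on [18, 95], BMI N(27.5, 5) kg/m²
  on [15, 50], diabetes 12%, smoking 20%, emergency surgery 25%, stoma
  plan 35%, viscus plan 75% (plausible laparotomy-population values; the
  source prints no baseline table in the economic paper), SSI 25.3% in
  the control arm with odds ratio 0.97 — SSI is a correlated covariate
  only, no causal device effect is simulated;
- **randomness**: one seed feeds named substreams (one per field) via
  seed-sequence spawning, so adding a field never perturbs earlier
  fields; identical config + seed gives byte-identical CSVs.

A separate **summary-calibrated mode** reconstructs per-patient
(total cost, QALY) pairs directly from the published arm aggregates:
gamma-shaped costs and normal QALYs with SD = printed SE × √n, affinely
rescaled so the per-arm *sample* mean and SD equal the published values
exactly (they are sample statistics of the source trial, so the
reconstructed dataset reproduces the published increments ΔC = £290,
ΔE = −0.00002 by construction; an expectation-only mode is available).
Costs and QALYs are independent within arm — the printed record carries
no correlation information — and the affine rescale can leave a handful
of slightly negative cost values, which is immaterial for mean-based
bootstrap statistics.

Two calibration surfaces cannot be reconciled: the printed resource-use
means × unit costs give arm totals ≈£5,676/£5,462, while the printed cost
table says £5,420/£5,130 (its components reflect the imputed analysis
dataset and possibly different critical-care pricing). The resource-use
generator is calibrated to the resource-use table and lands within a few
percent of the printed totals; exact reproduction of the printed
aggregates is the summary-calibrated mode's job.

What passing tests do **not** show about real data: no centre clustering
(21 hospitals are not modelled), no correlation between resource use and
utilities or survival beyond the stay/critical-care coupling, MCAR rather
than whatever the real mechanism was, and no wound-dressing costs (not
costed in the source either).

## Problem sizes

Library defaults are B = 1,000 bootstrap replicates and m = 20
imputations. The test suite exercises the full pipeline at reduced sizes
(trials of 60–160 patients, B = 100–300, m = 2–5) and the full 735-patient
trial for calibration checks; these sizes are chosen to keep the suite
fast while leaving every code path covered. The reproduction script runs
the full B = 1,000 bootstrap on the full 735-patient reconstruction.

## Known limitations

- The joint missingness structure and the source's QALY accrual
  convention are unknowable from the printed record (see above).
- BCa acceleration for pooled multiply-imputed clouds averages per-dataset
  jackknife accelerations; this is a pragmatic convention, not a derived
  estimator.
- The gamma-MLE standard error assumes an exact gamma law; it is reported
  alongside, never instead of, the distribution-free SE.
- Complete-case n cannot match the published 532 exactly without
  patient-level data; the predicate (which covariates count) is itself a
  package choice.
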