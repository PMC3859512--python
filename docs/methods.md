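# Methods

This note records the statistical model the package implements, the design
choices made where the design was genuinely open, the synthetic-data
conditions, and the numerical details that matter for reproducing results.

## Demand model

The unit of analysis is the *patient-year*: one row per patient per calendar
year with the annual count of transfused red-cell units as the outcome, plus
age (integer years at mid-year), weight (kg), sex, and a fixed splenectomy
flag. The marginal mean is log-linear,

    E[Y_it] = μ_it = exp(x_it'β),

with uncentred covariates, so exp(β) for age reads as the relative demand per
additional year of age from the natural origin, and the quadratic terms place
the demand peak at −β_lin/(2·β_quad). Centring covariates would change the
linear coefficients but neither the fitted means nor the peak location.

Estimation is by generalized estimating equations. Estimating-equation root:
Σ_i D_i'V_i⁻¹(y_i − μ_i) = 0 with D_i = A_i X_i, V_i = A_i^{1/2} R(α)
A_i^{1/2}, where R is the working correlation (identity, or exchangeable
with moment-estimated α from Pearson residuals). The coefficient covariance
is the robust sandwich B⁻¹MB⁻¹, which is consistent even when the working
correlation or the Poisson variance assumption is wrong; the Pearson scale
φ = Σr²_it/(N − p) is reported as the overdispersion summary. φ cancels
inside the sandwich, so robust standard errors do not depend on it.

The full fit is delegated to `statsmodels.GEE` (Poisson family,
Independence/Exchangeable covariance structures), started at the Poisson
maximum-likelihood solution so the independent-correlation root agrees with
plain IRLS to solver precision. Because statsmodels judges convergence on
the score norm — whose numerical floor scales with the data — the package
re-checks convergence on the relative coefficient change (≤ 1e-8 within 100
iterations) and raises with the iteration trace otherwise.

Inference is Wald-based throughout: 95% CIs as exp(β ± 1.96·SE_robust) and
two-sided p-values from the robust z statistic. (Score-based p-values would
be a defensible alternative; Wald matches the CI construction used in the
reports this package produces.)

### Exclusion filters

Before fitting, three filters run in order:

1. patient-years at age < 1 are dropped (transfusion therapy typically
   starts between 6 and 12 months; infant rows are unreliable), the patient
   is retained;
2. patients with an *irregular* transfusion pattern are excluded, made
   operational as: any calendar year strictly inside the patient's observed
   span with zero or missing demand. This is an interpretation — "irregular"
   has no unique definition — and it deliberately catches the
   every-other-year pattern;
3. patients with no recorded weight in any year are excluded (nothing to
   anchor the constant-z imputation).

## Weight transforms

The LMS reference table stores (sex, age-in-months, L, M, S) with linear
interpolation in age within sex; the CDC weight-for-age CSV dialect is read
unchanged. z = ((X/M)^L − 1)/(L·S) with the logarithmic branch used for
|L| < 1e-7; the inverse is algebraic, and the round-trip is exact to 1e-10
over the valid domain (tested by property).

Projection holds each patient's z fixed and reads the reference at the
target age, capped at 240 months; growth is treated as negligible from age
20. Two adult conventions coexist deliberately: an *observed* adult weight is
carried forward frozen (no reference noise is introduced), whereas *imputed*
adult weights use the adult-bin mean z applied at the age-20 reference
(the tables end there). Missing weights inside a patient's record are filled
from the nearest observed year's z (constant-z rule); cross-patient
imputation uses the mean z of the patient's age group, with 1-year bins
below 20, a single 20+ bin, and fallback to the nearest non-empty bin.
Reference lookups beyond the tabulated age range clamp to the nearest entry
with a warning rather than erroring, since the 20-year cap makes this the
common adult case.

## Model selection

Leave-one-out cross-validation leaves out one *patient-year observation* per
fold (not one patient), refits the working-correlation-specific GEE on the
rest, and scores the held-out row by absolute error; the comparison grid is
8 predictor sets × 2 working correlations, optionally extended with pairwise
interactions of {age, weight} × {female, splenectomy}. The exchangeable α is
re-estimated within every fold.

Fold refits use an in-package Fisher-scoring solver with the exchangeable
block inverse applied in closed form and step-halving on divergence of the
estimating-function norm, warm-started at the full-data solution. The solver
is tested to agree with statsmodels to ≤ 1e-8 on both structures and to be
warm-start invariant; warm starts change fold cost, not fold answers. This
keeps the full 16-cell grid on a ~1,700-row panel under half a minute.

The final model minimizes MAE subject to parsimony: among variants within
`parsimony_delta` (default 0.01 units) of the best score, the fewest
predictors win, with remaining ties broken by dropping years-of-transfusion
first, then interactions, then by MAE. The 0.01 default encodes the
judgement that MAE gaps of this size are negligible for demand planning.

## Demographic rates

*Incidence*: first-ever-registered patients during the estimation window
(which must start after the panel does, since earlier entrants cannot be
distinguished from prevalent cases) divided by stratum person-years from the
population history, per sex × age group {0–4, 5–9, 10–19, 20–59}; the
overall rate is also reported per 100,000.

*Mortality*: deaths at age ≥ 20 divided by adult person-years observed;
below 20 mortality is treated as zero (survival to adulthood is high in
regularly transfused cohorts, and recent long-term data are sparse).

## Cohort forecast

Mortality enters the projection as a deterministic expectation — survival
weights s_i(t) = Π_u (1 − m_u) over adult years — rather than sampled
deaths, so forecasts are bit-identical across reruns; a Monte-Carlo death
simulator exists purely as a testing oracle and agrees with the
expectation path within Monte-Carlo error.

New cases enter at the midpoint age of their stratum on 1 January of the
entry year and contribute a full year of demand (entry timing is a
convention; demand is annual). Each entering cohort carries its stratum's
mean weight z-score and splenectomy *prevalence* (as a fractional covariate,
not sampled), ages across strata, grows along the reference at fixed z, and
is attrited by adult mortality; demand accumulates across entry cohorts.

The 95% prediction interval for a year's total is
point ± 1.96·sqrt(g'Σ_β g + Σ_strata,entry-years (per-case demand)²·var(n)),
where g is the gradient of the total (existing + new) with respect to β —
so the covariance between the existing-patient and new-case components
through the shared coefficients is included — and var(n) comes from the
population projection's per-stratum coefficient of variation (default 0.02),
treated as independent across strata and entry years. The delta interval is
validated against a 10⁴-draw parametric bootstrap (5% relative tolerance on
the half-width).

Sensitivity scenarios rescale adult mortality by (1 − r·min(t,10)/10) for
r ∈ {0, 0.4, 0.8} — the reduction applies to adults only, because mortality
is adult-only throughout. Totals are verified to be monotone in r year by
year. Existing patients face no exits other than death (no emigration or
cure); that is a stated scenario limitation, not an oversight.

## Synthetic cohort: conditions and limits

The generator's defaults are the study conditions: 381 patients observed
2005–2009 (≈8.1% destined for the irregular-transfusion exclusion, ≈3.1%
for missing weights, mirroring the registry tallies), mean annual demand
≈38.7 units, generating coefficients equal to the published relative
demands (1.04, 0.9992, 1.04, 0.9997, 0.94, 0.85 on the RR scale; intercept
2.267, calibrated once so the included cohort's mean demand is ≈38.7),
Pearson scale 1.7, adult mortality 0.96%/yr, incidence 0.13/100,000/yr
against a ~7-million geometric-growth population, ages at entry uniform on
1–45 years (median ≈25, near the registry's 23), 50.4% female, 36.2%
splenectomised.

Overdispersion and correlation come from two multiplicative gamma
components on the Poisson mean: a patient-level frailty (variance
v_p = ρφ/μ̄, driving exchangeable-like within-patient correlation ρ) and an
independent observation-level component topping total heterogeneity up to
v_tot = (φ−1)/μ̄. This factorization honours a target scale φ and a target
correlation ρ simultaneously (feasible when ρ ≤ (φ−1)/φ, enforced at
config validation) and collapses to a single shared frailty when the
patient component carries everything. The estimation stage is never told
this mechanism. The published analysis gives no within-patient correlation
magnitude (its selected working structure was independent); the default
ρ = 0.2 is a free choice representing moderate persistent between-patient
heterogeneity.

What the generator does *not* emulate: transfusion scheduling within a
year, iron-chelation or hemoglobin dynamics, secular trends in demand,
incident splenectomies (the flag is fixed per patient, as the registry
recorded only status-by-2009), measurement error in weights, or emigration.
Passing tests therefore demonstrate correctness of the estimators and
projections under the assumed data-generating structure, not robustness to
real-registry artefacts beyond the two data-quality blemishes the generator
plants (irregular gaps, missing weights).

One deliberate mismatch: the generator's age–weight collinearity is
stronger than the registry's reported multicollinearity (VIFs near 4 for
age and weight rather than below 3), because synthetic weights track the
growth reference at a fixed z exactly. VIFs are reported, not enforced.

## Problem sizes in the test suite

Simulation-based checks run at reduced scale, chosen for fidelity first:
coverage uses 200 replicates of 120-patient × 3-year cohorts (fewer
clusters pushes the sandwich into its known small-sample downward bias;
120 keeps the check about correctness rather than about that bias),
cross-validation ranking uses 50 seeds of 50-patient cohorts, and the
Monte-Carlo oracles use 10⁴ replicates. The end-to-end demo runs the full
381-patient scenario with the complete 16-cell grid.

## Known limitations

- The sandwich covariance undercovers slightly below ~100 patients; no
  small-sample correction (e.g. Mancl–DeRouen) is applied.
- Incidence estimation cannot see entrants in the panel's first year, and
  with ~9 cases/year its CI is wide; the forecast treats the point rate as
  fixed (rate uncertainty is not in the prediction interval, only count
  forecast error).
- The independent-across-years treatment of population forecast errors
  understates interval width if census errors are serially correlated.
- Quadratic demand profiles extrapolate poorly far beyond the observed age
  range; the forecast horizon should stay within ~15 years of the fitting
  window.
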