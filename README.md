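# tmdemand

Forecasting blood demand from transfusion-dependent thalassemia-major (TM)
cohorts.

TM patients need red-cell transfusion every few weeks for life. Although a
registry may hold only a few hundred such patients, they can consume an
outsized share of a blood service's annual supply, so blood banks need
decade-scale forecasts of this demand to plan donor recruitment. `tmdemand`
implements a complete forecasting pipeline for this problem: it models each
patient's annual red-cell demand from their demographics, projects every
patient's body weight forward along a growth reference, and aggregates
demand from the surviving cohort plus expected incident cases, with
prediction intervals.

## The model

**Demand model.** Annual demand counts `Y_it` (units of red cells for
patient *i* in year *t*) follow a marginal Poisson regression with log link,

    E[Y_it] = exp(β₀ + β₁·age + β₂·age² + β₃·weight + β₄·weight²
                  + β₅·female + β₆·splenectomy),

estimated by generalized estimating equations (GEE) with an independent or
exchangeable working correlation, a Pearson-based overdispersion scale
φ = Σr²/(N−p), and the robust sandwich covariance B⁻¹MB⁻¹ for the
coefficients. `exp(β)` is reported as the *relative blood demand* per unit
covariate change; quadratic age and weight effects give an inverted-U demand
profile peaking at −β₁/(2β₂).

**Model selection.** Candidate predictor sets (± quadratic terms, ± years of
transfusion, ± interactions, × two working correlations) are compared by
leave-one-out cross-validation scored with mean absolute prediction error
(MAE), and the final model is the most parsimonious one within a small MAE
tolerance of the optimum.

**Weight projection.** Observed weights are converted to z-scores against a
weight-for-age LMS reference (`z = ((X/M)^L − 1)/(L·S)`), each patient's z is
held constant, and future weights are read off the reference at future ages;
growth is treated as negligible from age 20.

**Cohort forecast.** Existing patients are aged forward with survival
weights `s_i(t) = Π(1 − m_u)` (constant adult mortality `m`, optionally
reduced linearly over ten years in sensitivity scenarios). Incident cases
arrive at sex/age-group-specific incidence rates applied to official
population projections and accumulate across entry cohorts. 95% prediction
intervals come from the delta method: `var = g'Σ_β g + Σ (per-case
demand)²·var(count)`, combining coefficient uncertainty with population
forecast error.

Because patient-level transfusion registries are confidential, the package
includes a first-class synthetic-cohort generator
(`tmdemand.synthetic_data`) reproducing the statistical structure this
analysis assumes — overdispersed correlated counts, inverted-U covariate
effects, growth-referenced weights, adult mortality, and incident arrivals —
so the entire pipeline is testable end to end without any private data.

## Worked example

```python
import tmdemand as td
from tmdemand import synthetic_data as sd

lms = sd.generate_lms_reference()
cohort = sd.generate_cohort(sd.GeneratorConfig(seed=1), lms)
panel, log = td.apply_exclusions(cohort.panel)
panel, _ = td.backfill_weights(panel, lms)
print(log.summary())

fit = td.fit_model(panel, td.ModelVariant(("age2", "weight2"), "independent"))
print(td.relative_demand_table(fit).round(4).to_string(index=False))
print(f"Pearson scale: {fit.scale:.2f}")
print(f"peak demand at age {td.peak_covariate(fit, 'age'):.1f} y, "
      f"weight {td.peak_covariate(fit, 'weight'):.1f} kg")
```

prints

```
{'irregular_patients': 31, 'missing_weight_patients': 12, 'infant_rows_dropped': 0}
       term     rr  ci_lo  ci_hi      p
        age 1.0394 1.0301 1.0488 0.0000
       age2 0.9992 0.9991 0.9994 0.0000
     weight 1.0408 1.0353 1.0463 0.0000
    weight2 0.9997 0.9997 0.9997 0.0000
     female 0.9506 0.9226 0.9794 0.0009
splenectomy 0.8410 0.8178 0.8648 0.0000
Pearson scale: 1.74
peak demand at age 24.2 y, weight 66.3 kg
```

The exclusion filters removed 31 patients with irregular transfusion
patterns (a zero-demand year inside their observation span) and 12 with no
recorded weight. The fitted relative demands say, for example, that female
patients use about 5% fewer units per year and splenectomised patients about
16% fewer, and that demand peaks for patients in their mid-twenties —
exactly the structure the generator encodes.

The full pipeline (simulate → exclusions → cross-validated selection → fit →
rate estimation → scenario forecasts) runs from a shell:

```sh
tmdemand run --out demo-out --seed 0
```

which finishes in about half a minute and prints a scenario summary like

```
baseline: 14017 (2010) -> 17226 (2024) [95% PI 16888, 17563], new-case share 28.9%
mort-40:  ...
mort-80:  ...
```

along with `scores.csv` (the 16-cell cross-validation table), `table2.csv`
(relative demands), `fit.json`, and `forecast.csv` in the output directory.

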