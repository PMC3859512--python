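"""Synthetic patient panels, growth references, and population projections.

The confidential transfusion registry behind this analysis cannot be
redistributed, so every downstream stage is exercised on cohorts drawn from a
generator that reproduces the registry's published statistical structure:
annual red-cell demand counts with mean about 38.7 units/yr, inverted-U age
and weight effects on the log mean, lower demand for females and
splenectomised patients, moderate overdispersion (Pearson scale about 1.7),
within-patient correlation, roughly 1%/yr adult mortality, and an incidence
of new transfusion-dependent cases near 0.13 per 100,000 per year.

Overdispersion and correlation are induced by multiplicative gamma
heterogeneity on the Poisson mean: a patient-level frailty shared across a
patient's years (driving exchangeable-like correlation) and an independent
observation-level component (topping up the marginal variance to the target
scale). The estimation stage is never told this mechanism.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import growth as gr
from .projection import AGE_GROUPS, PopulationProjection

__all__ = [
    "GeneratorConfig", "SyntheticCohort", "LMSCurveParams",
    "generate_cohort", "generate_lms_reference", "generate_population_projection",
    "default_beta",
]


def default_beta() -> dict:
    """Generating coefficients on the log scale.

    Slopes mirror the published relative-demand ratios (1.04/yr and 0.9992
    for age and age^2, 1.04/kg and 0.9997 for weight and weight^2, 0.94
    female, 0.85 splenectomy); the intercept is calibrated once so the
    default cohort's mean annual demand is about 38.7 units.
    """
    return {
        "const": 2.267,
        "age": math.log(1.04),
        "age2": math.log(0.9992),
        "weight": math.log(1.04),
        "weight2": math.log(0.9997),
        "female": math.log(0.94),
        "splenectomy": math.log(0.85),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic registry.

    Defaults emulate the reference registry's scale: 381 patients observed
    2005-2009, ~8.1% with irregular transfusion patterns and ~3.1% with no
    recorded weights (both destined for exclusion), overdispersion scale 1.7,
    adult mortality 0.96%/yr, incidence 0.13/100,000/yr against a ~7 million
    population.
    """

    n_patients: int = 381
    years: tuple[int, int] = (2005, 2009)
    beta: dict = field(default_factory=default_beta)
    scale: float = 1.7
    within_corr: float = 0.2
    mortality_rate_adult: float = 0.0096
    incidence_per_100k: float = 0.13
    seed: int = 0
    # cohort composition
    female_frac: float = 0.504
    splenectomy_prev: float = 0.362
    age_max_at_start: int = 45
    # data-quality blemishes the exclusion filters must handle
    frac_irregular: float = 0.081
    frac_missing_all_weight: float = 0.031
    frac_missing_weight_row: float = 0.03
    # population backdrop for incident-case arrivals
    population_base: dict = field(default_factory=lambda: {
        "0-4": 150_000.0, "5-9": 150_000.0,
        "10-19": 400_000.0, "20-59": 2_800_000.0,
    })
    population_growth: float = 0.009
    population_cv: float = 0.02

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.years[1] - self.years[0] < 1:
            raise ValueError("years must span at least 2 calendar years")
        if self.scale < 1:
            raise ValueError("overdispersion scale must be >= 1")
        if not 0 <= self.within_corr < 1:
            raise ValueError("within_corr must be in [0, 1)")
        for name in ("mortality_rate_adult", "female_frac", "splenectomy_prev",
                     "frac_irregular", "frac_missing_all_weight",
                     "frac_missing_weight_row"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.scale > 1 and self.within_corr * self.scale > self.scale - 1 + 1e-12:
            raise ValueError(
                "within_corr too large for the requested scale: "
                f"need within_corr <= (scale-1)/scale = {(self.scale - 1) / self.scale:.3f}"
            )
        if self.scale == 1 and self.within_corr > 0:
            raise ValueError("within_corr > 0 requires scale > 1")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticCohort:
    """A generated registry: patient roster, patient-year panel, and the
    generating configuration (the truth downstream stages try to recover)."""

    roster: pd.DataFrame
    panel: pd.DataFrame
    truth: GeneratorConfig

    def write_panel_csv(self, path, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.panel.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# LMS reference generator


@dataclass(frozen=True)
class LMSCurveParams:
    """Smooth weight-for-age curve for one sex: an exponential-saturation
    childhood component plus a logistic adolescent spurt, with a Box-Cox L
    and a linearly drifting coefficient of variation."""

    birth_kg: float = 3.4
    childhood_gain_kg: float = 30.0
    childhood_tau_mo: float = 70.0
    spurt_gain_kg: float = 34.0
    spurt_center_mo: float = 168.0
    spurt_width_mo: float = 22.0
    L: float = -1.2
    S0: float = 0.11
    S_slope: float = 0.03  # S at 240 mo = S0 + S_slope


DEFAULT_LMS_PARAMS = {
    "M": LMSCurveParams(),
    "F": LMSCurveParams(spurt_gain_kg=22.0, spurt_center_mo=140.0,
                        childhood_gain_kg=28.0),
}


def generate_lms_reference(params: dict | None = None,
                           age_step_mo: float = 3.0) -> gr.LMSReference:
    """Tabulate a synthetic weight-for-age LMS reference over 0-240 months.

    Stands in for a national growth reference; same column dialect, strictly
    increasing median. Raises if the supplied curve is not monotone.
    """
    params = params or DEFAULT_LMS_PARAMS
    rows = []
    ages = np.arange(0.0, 240.0 + 1e-9, age_step_mo)
    for sex, p in params.items():
        M = (
            p.birth_kg
            + p.childhood_gain_kg * (1.0 - np.exp(-ages / p.childhood_tau_mo))
            + p.spurt_gain_kg / (1.0 + np.exp(-(ages - p.spurt_center_mo) / p.spurt_width_mo))
        )
        if np.any(np.diff(M) <= 0):
            raise ValueError(f"median weight curve not strictly increasing for sex {sex}")
        S = p.S0 + p.S_slope * ages / 240.0
        for a, m, s in zip(ages, M, S):
            rows.append({"sex": sex, "agemos": a, "L": p.L, "M": m, "S": s})
    return gr.LMSReference(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Population projection generator


def generate_population_projection(years, base_counts: dict, growth_rate: float,
                                   cv: float = 0.02) -> PopulationProjection:
    """Geometric-growth population counts per (year, sex, age_group), each
    annotated with a forecast coefficient of variation.

    ``base_counts`` maps age_group -> per-sex count in the first year (or
    (sex, age_group) -> count for asymmetric populations).
    """
    years = list(years)
    rows = []
    for year in years:
        factor = (1.0 + growth_rate) ** (year - years[0])
        for sex in ("M", "F"):
            for grp in AGE_GROUPS:
                base = base_counts.get((sex, grp), base_counts.get(grp))
                if base is None:
                    raise ValueError(f"base_counts missing age group {grp!r}")
                if base < 0:
                    raise ValueError("population counts must be non-negative")
                rows.append({
                    "year": int(year), "sex": sex, "age_group": grp,
                    "count": base * factor, "cv": cv,
                })
    return PopulationProjection(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Cohort generator


def _frailty_variances(config: GeneratorConfig, mu_ref: float):
    """Split the overdispersion target into patient- and observation-level
    gamma variances.

    Marginal variance mu(1 + v_tot mu) gives Pearson scale ~ 1 + v_tot mu_ref;
    within-patient demand correlation ~ v_p mu_ref / scale.
    """
    if config.scale <= 1.0 or mu_ref <= 0:
        return 0.0, 0.0
    v_tot = (config.scale - 1.0) / mu_ref
    v_p = config.within_corr * config.scale / mu_ref
    v_p = min(v_p, v_tot)
    v_o = (v_tot - v_p) / (1.0 + v_p)
    return v_p, v_o


def _linear_predictor(beta: dict, age, weight, female, splen):
    lp = np.full(np.shape(age), beta.get("const", 0.0), dtype=float)
    lp += beta.get("age", 0.0) * age + beta.get("age2", 0.0) * age**2
    lp += beta.get("weight", 0.0) * weight + beta.get("weight2", 0.0) * weight**2
    lp += beta.get("female", 0.0) * female + beta.get("splenectomy", 0.0) * splen
    return lp


def generate_cohort(config: GeneratorConfig,
                    lms: gr.LMSReference | None = None) -> SyntheticCohort:
    """Draw a synthetic registry under ``config``.

    Patients carry a fixed sex, splenectomy flag and weight z-score; annual
    demand is overdispersed Poisson around exp(x'beta); adults (age >= 20)
    die at the configured annual rate; incident cases enter at age 1 at the
    configured population incidence. Identical config (incl. seed) gives an
    identical cohort.
    """
    if lms is None:
        lms = generate_lms_reference()
    for sex in ("M", "F"):
        lo, hi = lms.age_range(sex)
        if lo > 12.0 or hi < 240.0:
            raise gr.LMSCoverageError(
                f"LMS reference must cover 12-240 months for sex {sex}; "
                f"has [{lo}, {hi}]"
            )
    rng = np.random.default_rng(config.seed)
    start, end = config.years
    n = config.n_patients

    # --- roster: prevalent patients, present from the first panel year
    # (new arrivals during the window come only from the incident stream)
    age_start = rng.integers(1, config.age_max_at_start + 1, size=n)
    sex = np.where(rng.random(n) < config.female_frac, "F", "M")
    splen = (rng.random(n) < config.splenectomy_prev).astype(int)
    z = rng.normal(0.0, 1.0, size=n)
    birth_year = start - age_start
    ids = np.array([f"P{i:04d}" for i in range(n)])

    # --- incident patients entering at age 1 in each year after the first
    inc_rate = config.incidence_per_100k / 1e5
    total_pop0 = 2.0 * sum(config.population_base.values())
    new_ids, new_sex, new_splen, new_z, new_birth, new_entry = [], [], [], [], [], []
    k = 0
    for year in range(start + 1, end + 1):
        pop = total_pop0 * (1.0 + config.population_growth) ** (year - start)
        n_new = rng.poisson(inc_rate * pop)
        for _ in range(n_new):
            new_ids.append(f"N{k:04d}")
            new_sex.append("F" if rng.random() < config.female_frac else "M")
            new_splen.append(0)  # incident infants have intact spleens
            new_z.append(rng.normal())
            new_birth.append(year - 1)
            new_entry.append(year)
            k += 1

    ids = np.concatenate([ids, np.array(new_ids, dtype=object)])
    sex = np.concatenate([sex, np.array(new_sex, dtype=object)])
    splen = np.concatenate([splen, np.array(new_splen, dtype=int)])
    z = np.concatenate([z, np.array(new_z, dtype=float)])
    birth_year = np.concatenate([birth_year, np.array(new_birth, dtype=int)])
    n_all = len(ids)

    # --- panel skeleton with deterministic covariates
    recs = []
    for i in range(n_all):
        for year in range(start, end + 1):
            age = year - birth_year[i]
            if age < 1:
                continue
            recs.append((ids[i], i, year, int(age)))
    skel = pd.DataFrame(recs, columns=["patient_id", "_i", "year", "age_years"])
    if len(skel) == 0:
        empty_panel = pd.DataFrame(columns=[
            "patient_id", "year", "sex", "age_years", "weight_kg",
            "splenectomy", "units", "death_year",
        ])
        empty_roster = pd.DataFrame(columns=[
            "patient_id", "sex", "birth_year", "splenectomy", "z", "death_year",
        ])
        return SyntheticCohort(roster=empty_roster, panel=empty_panel, truth=config)
    sexes = sex[skel["_i"].to_numpy()]
    ages = skel["age_years"].to_numpy(dtype=float)
    zs = z[skel["_i"].to_numpy()]
    weight = np.empty(len(skel))
    for s in ("M", "F"):
        m = sexes == s
        if m.any():
            L, M, S = lms.params(s, np.minimum(ages[m], gr.ADULT_AGE_YEARS) * 12.0)
            weight[m] = gr.lms_inverse(zs[m], L, M, S)
    female = (sexes == "F").astype(float)
    splen_row = splen[skel["_i"].to_numpy()].astype(float)

    mu = np.exp(_linear_predictor(config.beta, ages, weight, female, splen_row))
    mu_ref = float(mu.mean()) if len(mu) else 0.0
    v_p, v_o = _frailty_variances(config, mu_ref)
    frail_p = (
        rng.gamma(1.0 / v_p, v_p, size=n_all) if v_p > 0 else np.ones(n_all)
    )
    frail_o = (
        rng.gamma(1.0 / v_o, v_o, size=len(skel)) if v_o > 0 else np.ones(len(skel))
    )
    units = rng.poisson(frail_p[skel["_i"].to_numpy()] * frail_o * mu)

    panel = skel.copy()
    panel["sex"] = sexes
    panel["weight_kg"] = weight
    panel["splenectomy"] = splen_row.astype(int)
    panel["units"] = units.astype(int)

    # --- adult mortality: sweep years in order, truncating panels at death
    death_year = np.full(n_all, np.nan)
    for year in range(start, end + 1):
        age_now = year - birth_year
        at_risk = (age_now >= 20) & (np.isnan(death_year))
        dies = at_risk & (rng.random(n_all) < config.mortality_rate_adult)
        death_year[dies] = year
    died_i = np.flatnonzero(~np.isnan(death_year))
    if len(died_i):
        dy = pd.Series(death_year, index=np.arange(n_all))
        keep = panel["year"].to_numpy() <= dy.reindex(panel["_i"]).fillna(np.inf).to_numpy()
        panel = panel.loc[keep]
    panel["death_year"] = pd.array(
        [death_year[i] if not np.isnan(death_year[i]) else pd.NA
         for i in panel["_i"]],
        dtype="Int64",
    )

    # --- data-quality blemishes (targets for the exclusion filters)
    prevalent = np.arange(config.n_patients)
    spans = panel.groupby("_i")["year"].agg(["min", "max", "count"])
    eligible = [
        i for i in prevalent
        if i in spans.index and spans.loc[i, "count"] >= 3
    ]
    n_irr = int(round(config.frac_irregular * config.n_patients))
    irr = (
        rng.choice(eligible, size=min(n_irr, len(eligible)), replace=False)
        if eligible else np.array([], dtype=int)
    )
    for i in irr:
        yrs = panel.loc[panel["_i"] == i, "year"].to_numpy()
        mid = yrs[len(yrs) // 2]
        panel.loc[(panel["_i"] == i) & (panel["year"] == mid), "units"] = 0

    rest = [i for i in eligible if i not in set(irr.tolist())]
    n_miss = int(round(config.frac_missing_all_weight * config.n_patients))
    miss_all = (
        rng.choice(rest, size=min(n_miss, len(rest)), replace=False)
        if rest else np.array([], dtype=int)
    )
    wcol = panel["weight_kg"].to_numpy().copy()
    wcol[np.isin(panel["_i"].to_numpy(), miss_all)] = np.nan
    # sporadic missing single-year weights elsewhere
    sporadic = (rng.random(len(panel)) < config.frac_missing_weight_row) & ~np.isin(
        panel["_i"].to_numpy(), miss_all
    )
    wcol[sporadic] = np.nan
    panel["weight_kg"] = wcol

    roster = pd.DataFrame({
        "patient_id": ids,
        "sex": sex,
        "birth_year": birth_year,
        "splenectomy": splen,
        "z": z,
        "death_year": pd.array(
            [int(d) if not np.isnan(d) else pd.NA for d in death_year],
            dtype="Int64",
        ),
    })
    panel = (
        panel.drop(columns=["_i"])
        [["patient_id", "year", "sex", "age_years", "weight_kg",
          "splenectomy", "units", "death_year"]]
        .sort_values(["patient_id", "year"])
        .reset_index(drop=True)
    )
    return SyntheticCohort(roster=roster, panel=panel, truth=config)
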