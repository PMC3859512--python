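"""Cohort demand forecasting: age the existing patients forward with projected
weights and mortality attrition, add incident cases from population
projections, and attach delta-method prediction intervals plus
mortality-reduction sensitivity scenarios.

All projections are deterministic expectations: mortality enters as a
survival weight s_i(t) = prod_u (1 - m_u) over adult years, not as sampled
deaths, so identical inputs give bit-identical forecast tables. A Monte-Carlo
death mode exists for oracle testing only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth as gr
from .gee import GEEFit

#: Sex x age-group strata used for incidence and population projections.
AGE_GROUPS = ("0-4", "5-9", "10-19", "20-59")
AGE_GROUP_BOUNDS = {"0-4": (0, 4), "5-9": (5, 9), "10-19": (10, 19), "20-59": (20, 59)}
SEXES = ("M", "F")

Z95 = 1.959963984540054  # normal 97.5% point


def age_group_of(age: float) -> str | None:
    for g, (lo, hi) in AGE_GROUP_BOUNDS.items():
        if lo <= age <= hi:
            return g
    return None


def stratum_midpoint_age(group: str) -> float:
    lo, hi = AGE_GROUP_BOUNDS[group]
    return (lo + hi) / 2.0


@dataclass
class PopulationProjection:
    """Projected counts per (year, sex, age_group), each with a forecast
    coefficient of variation.

    ``table`` columns: year, sex, age_group, count, cv.
    """

    table: pd.DataFrame
    _idx: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        t = self.table.copy()
        required = {"year", "sex", "age_group", "count", "cv"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        if (t["count"] < 0).any():
            raise ValueError("population counts must be non-negative")
        t["sex"] = gr._normalize_sex(t["sex"].to_numpy())
        self.table = t.reset_index(drop=True)
        for row in t.itertuples(index=False):
            self._idx[(int(row.year), row.sex, row.age_group)] = (
                float(row.count), float(row.cv)
            )

    @classmethod
    def read_csv(cls, path) -> "PopulationProjection":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, header_lines=None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, index=False)

    def years(self) -> list[int]:
        return sorted(self.table["year"].unique().tolist())

    def count(self, year: int, sex: str, age_group: str) -> float:
        return self._idx[(int(year), sex, age_group)][0]

    def cv(self, year: int, sex: str, age_group: str) -> float:
        return self._idx[(int(year), sex, age_group)][1]


@dataclass
class IncidenceRates:
    """Annual rate of new transfusion-dependent registrations per person,
    by (sex, age_group)."""

    rates: dict  # (sex, age_group) -> rate
    n_cases: int = 0
    person_years: float = 0.0

    def __post_init__(self):
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("incidence rates must be non-negative")

    def rate(self, sex: str, age_group: str) -> float:
        return self.rates.get((sex, age_group), 0.0)

    @property
    def overall_per_100k(self) -> float:
        if self.person_years == 0:
            return 0.0
        return 1e5 * self.n_cases / self.person_years


@dataclass
class MortalityModel:
    """Constant annual death probability for patients aged >= 20, optionally
    reduced linearly by fraction ``reduction`` over ``window_years``."""

    adult_rate: float
    reduction: float = 0.0
    window_years: int = 10

    def __post_init__(self):
        if not 0 <= self.adult_rate <= 1:
            raise ValueError("adult_rate must be a probability")
        if not 0 <= self.reduction <= 1:
            raise ValueError("reduction must be in [0, 1]")

    def rate_in(self, years_ahead: int) -> float:
        """Effective adult mortality in forecast year ``years_ahead`` (1-based)."""
        frac = min(max(years_ahead, 0), self.window_years) / self.window_years
        return self.adult_rate * (1.0 - self.reduction * frac)


# ---------------------------------------------------------------------------
# Rate estimation from the observed panel


def estimate_incidence(panel: pd.DataFrame, population: PopulationProjection,
                       window: tuple[int, int]) -> IncidenceRates:
    """Sex- and age-group-specific incidence of new transfusion-dependent
    cases: first-ever-registered patients in ``window`` over stratum
    person-years from the population history.

    Patients already present in the panel's first year are prevalent, not
    incident, so the window must start after the panel does.
    """
    lo, hi = window
    panel_start = int(panel["year"].min())
    if lo <= panel_start:
        raise ValueError(
            "incidence window must start after the panel's first year "
            "(earlier entrants cannot be distinguished from prevalent cases)"
        )
    first = panel.groupby("patient_id").agg(
        first_year=("year", "min"), sex=("sex", "first")
    )
    entry_age = panel.groupby("patient_id").apply(
        lambda s: int(s.loc[s["year"].idxmin(), "age_years"]),
        include_groups=False,
    )
    first["entry_age"] = entry_age

    cases: dict = {}
    total_cases = 0
    for row in first.itertuples():
        if not (lo <= row.first_year <= hi):
            continue
        sex = gr._normalize_sex(row.sex)[0]
        grp = age_group_of(row.entry_age)
        if grp is None:
            continue
        cases[(sex, grp)] = cases.get((sex, grp), 0) + 1
        total_cases += 1

    rates: dict = {}
    total_py = 0.0
    for sex in SEXES:
        for grp in AGE_GROUPS:
            py = 0.0
            for year in range(lo, hi + 1):
                try:
                    py += population.count(year, sex, grp)
                except KeyError:
                    pass
            total_py += py
            k = cases.get((sex, grp), 0)
            if py == 0:
                if k > 0:
                    import warnings

                    warnings.warn(
                        f"stratum ({sex},{grp}) has cases but zero person-years; "
                        "rate set to 0"
                    )
                rates[(sex, grp)] = 0.0
            else:
                rates[(sex, grp)] = k / py
    return IncidenceRates(rates=rates, n_cases=total_cases, person_years=total_py)


def estimate_mortality(panel: pd.DataFrame) -> float:
    """Adult annual mortality: deaths at age >= 20 over adult person-years
    observed in the panel."""
    adult_rows = panel[panel["age_years"] >= 20]
    adult_py = float(len(adult_rows))
    if adult_py == 0:
        raise ValueError("no adult person-years observed")
    deaths = 0
    if "death_year" in panel.columns:
        per_patient = panel.dropna(subset=["death_year"]).groupby("patient_id").agg(
            death_year=("death_year", "first"),
            birth=("year", "first"),
        )
        for pid, row in per_patient.iterrows():
            sub = panel[panel["patient_id"] == pid]
            age_at_death = int(row.death_year) - (
                int(sub["year"].iloc[0]) - int(sub["age_years"].iloc[0])
            )
            if age_at_death >= 20:
                deaths += 1
    return deaths / adult_py


# ---------------------------------------------------------------------------
# Forward projection


def baseline_roster(panel: pd.DataFrame, base_year: int,
                    lms: gr.LMSReference) -> pd.DataFrame:
    """Existing patients as of ``base_year``: one row per patient alive and
    observed that year, with age, weight and z-score at base."""
    sub = panel[panel["year"] == base_year].copy()
    if "death_year" in sub.columns:
        dead = pd.to_numeric(sub["death_year"], errors="coerce") <= base_year
        sub = sub[~dead.fillna(False)]
    first = panel.groupby("patient_id")["year"].min()
    roster = pd.DataFrame({
        "patient_id": sub["patient_id"].to_numpy(),
        "sex": gr._normalize_sex(sub["sex"].to_numpy()),
        "age": sub["age_years"].to_numpy(dtype=float),
        "weight": sub["weight_kg"].to_numpy(dtype=float),
        "female": (gr._normalize_sex(sub["sex"].to_numpy()) == "F").astype(float),
        "splenectomy": sub["splenectomy"].to_numpy(dtype=float),
        "first_year": first.reindex(sub["patient_id"]).to_numpy(),
    })
    roster["z"] = [
        gr.zscore_at_age(w, s, a, lms)
        for w, s, a in zip(roster["weight"], roster["sex"], roster["age"])
    ]
    return roster


def _weight_at(z: float, sex: str, age: float, lms: gr.LMSReference) -> float:
    L, M, S = lms.params(sex, min(age, gr.ADULT_AGE_YEARS) * 12.0)
    return float(gr.lms_inverse(z, L, M, S))


def _design_matrix(fit: GEEFit, cov: pd.DataFrame) -> np.ndarray:
    from .gee import term_values

    cols = []
    for name in fit.params.index:
        if name == "const":
            cols.append(np.ones(len(cov)))
        else:
            cols.append(term_values(cov, name))
    return np.column_stack(cols)


def project_existing(fit: GEEFit, roster: pd.DataFrame, lms: gr.LMSReference,
                     mortality: MortalityModel, horizon: list[int],
                     base_year: int):
    """Expected demand from existing patients per horizon year, with the
    gradient d(total)/d(beta) retained for prediction intervals.

    Year t total = sum_i s_i(t) exp(x_i(t)'beta) where s_i multiplies
    (1 - m_u) over each adult year u <= t and x_i(t) carries the aged
    covariates and constant-z projected weight (adults keep their observed
    weight).

    Returns ``(units, gradients)``: a Series indexed by year and an
    (n_years x p) DataFrame.
    """
    horizon = list(horizon)
    n = len(roster)
    survival = np.ones(n)
    base_age = roster["age"].to_numpy(dtype=float)
    base_weight = roster["weight"].to_numpy(dtype=float)
    z = roster["z"].to_numpy(dtype=float)
    sexes = roster["sex"].to_numpy()
    units, grads = {}, {}
    for year in horizon:
        t = year - base_year
        if t < 1:
            raise ValueError("horizon years must follow the base year")
        age = base_age + t
        adult = age >= gr.ADULT_AGE_YEARS
        survival = survival * np.where(adult, 1.0 - mortality.rate_in(t), 1.0)
        weight = np.where(
            base_age >= gr.ADULT_AGE_YEARS,
            base_weight,
            [_weight_at(zi, s, a, lms) for zi, s, a in zip(z, sexes, age)],
        )
        cov = pd.DataFrame({
            "age": age,
            "weight": weight,
            "female": roster["female"].to_numpy(dtype=float),
            "splenectomy": roster["splenectomy"].to_numpy(dtype=float),
            "year_of_transfusion": year - roster["first_year"].to_numpy(dtype=float),
        })
        X = _design_matrix(fit, cov)
        mu = np.exp(X @ fit.params.to_numpy())
        w = survival * mu
        units[year] = float(w.sum())
        grads[year] = X.T @ w
    grad_df = pd.DataFrame(grads, index=fit.params.index).T
    return pd.Series(units, name="existing_units"), grad_df


def simulate_existing_deaths(fit: GEEFit, roster: pd.DataFrame,
                             lms: gr.LMSReference, mortality: MortalityModel,
                             horizon: list[int], base_year: int,
                             n_replicates: int, rng) -> np.ndarray:
    """Monte-Carlo companion to :func:`project_existing`: sample adult deaths
    at the effective rates and return realized totals per (replicate, year).
    Oracle-testing aid, not part of the forecasting path."""
    horizon = list(horizon)
    n = len(roster)
    base_age = roster["age"].to_numpy(dtype=float)
    alive = np.ones((n_replicates, n), dtype=bool)
    out = np.zeros((n_replicates, len(horizon)))
    for k, year in enumerate(horizon):
        t = year - base_year
        age = base_age + t
        adult = age >= gr.ADULT_AGE_YEARS
        dies = rng.random((n_replicates, n)) < mortality.rate_in(t)
        alive &= ~(dies & adult)
        # recompute per-patient mu for this year (no mortality weighting)
        z = roster["z"].to_numpy(dtype=float)
        sexes = roster["sex"].to_numpy()
        weight = np.where(
            base_age >= gr.ADULT_AGE_YEARS,
            roster["weight"].to_numpy(dtype=float),
            [_weight_at(zi, s, a, lms) for zi, s, a in zip(z, sexes, age)],
        )
        cov = pd.DataFrame({
            "age": age,
            "weight": weight,
            "female": roster["female"].to_numpy(dtype=float),
            "splenectomy": roster["splenectomy"].to_numpy(dtype=float),
            "year_of_transfusion": year - roster["first_year"].to_numpy(dtype=float),
        })
        X = _design_matrix(fit, cov)
        mu = np.exp(X @ fit.params.to_numpy())
        out[:, k] = alive @ mu
    return out


def group_covariates(panel: pd.DataFrame, lms: gr.LMSReference) -> pd.DataFrame:
    """Per (sex, age_group) means of the explanatory variables from the
    fitted cohort: mean weight z-score and splenectomy prevalence. Used as
    the representative covariates of entering new-case cohorts; empty strata
    fall back to the nearest non-empty age group within sex."""
    p = panel.copy()
    p["sex"] = gr._normalize_sex(p["sex"].to_numpy())
    p["z"] = [
        gr.zscore_at_age(w, s, a, lms)
        for w, s, a in zip(p["weight_kg"], p["sex"], p["age_years"])
    ]
    rows = []
    for sex in SEXES:
        sub_sex = p[p["sex"] == sex]
        for grp in AGE_GROUPS:
            lo, hi = AGE_GROUP_BOUNDS[grp]
            sub = sub_sex[(sub_sex["age_years"] >= lo) & (sub_sex["age_years"] <= hi)]
            if len(sub) == 0:
                sub = sub_sex if len(sub_sex) else p
            rows.append({
                "sex": sex,
                "age_group": grp,
                "z": float(sub["z"].mean()),
                "splenectomy": float(sub["splenectomy"].mean()),
            })
    return pd.DataFrame(rows)


def project_new_cases(fit: GEEFit, incidence: IncidenceRates,
                      population: PopulationProjection,
                      group_covs: pd.DataFrame, lms: gr.LMSReference,
                      mortality: MortalityModel, horizon: list[int],
                      base_year: int):
    """Expected demand from incident cases, accumulating entry cohorts.

    Stratum g contributes n_g(tau) = rate_g x population_g(tau) entrants in
    year tau at the stratum midpoint age; each entering cohort keeps the
    stratum mean z and splenectomy prevalence, grows along the reference
    curve, and is attrited by adult mortality. Count forecast error
    (population CV) is propagated as an independent variance per stratum and
    entry year.

    Returns ``(units, gradients, count_variance)`` per horizon year.
    """
    horizon = list(horizon)
    p = len(fit.params)
    units = {y: 0.0 for y in horizon}
    grads = {y: np.zeros(p) for y in horizon}
    countvar = {y: 0.0 for y in horizon}
    gc = group_covs.set_index(["sex", "age_group"])

    for tau in horizon:
        for sex in SEXES:
            for grp in AGE_GROUPS:
                rate = incidence.rate(sex, grp)
                if rate == 0:
                    continue
                try:
                    pop = population.count(tau, sex, grp)
                    cv = population.cv(tau, sex, grp)
                except KeyError as exc:
                    raise ValueError(
                        f"population projection missing stratum {exc}"
                    ) from exc
                n_enter = rate * pop
                var_n = (rate * cv * pop) ** 2
                if (sex, grp) not in gc.index:
                    raise ValueError(f"missing stratum covariates for ({sex},{grp})")
                z = float(gc.loc[(sex, grp), "z"])
                splen = float(gc.loc[(sex, grp), "splenectomy"])
                entry_age = stratum_midpoint_age(grp)
                survival = 1.0
                for year in horizon:
                    if year < tau:
                        continue
                    age = entry_age + (year - tau)
                    if age >= gr.ADULT_AGE_YEARS:
                        survival *= 1.0 - mortality.rate_in(year - base_year)
                    weight = _weight_at(z, sex, age, lms)
                    cov = pd.DataFrame({
                        "age": [age],
                        "weight": [weight],
                        "female": [1.0 if sex == "F" else 0.0],
                        "splenectomy": [splen],
                        "year_of_transfusion": [float(year - tau)],
                    })
                    x = _design_matrix(fit, cov)[0]
                    mu = float(np.exp(x @ fit.params.to_numpy()))
                    d = survival * mu  # demand per entrant
                    units[year] += n_enter * d
                    grads[year] += n_enter * d * x
                    countvar[year] += var_n * d * d
    grad_df = pd.DataFrame(grads, index=fit.params.index).T
    return (
        pd.Series(units, name="newcase_units"),
        grad_df,
        pd.Series(countvar, name="count_variance"),
    )


def delta_method_pi(point: float, gradient: np.ndarray, robust_cov: np.ndarray,
                    count_variance: float = 0.0, level: float = 0.95):
    """First-order prediction interval for a projected total.

    var = g' Sigma_beta g + count_variance; interval = point +/- z * sqrt(var).
    """
    cov = np.asarray(robust_cov, dtype=float)
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError("covariance matrix is not positive semi-definite")
    g = np.asarray(gradient, dtype=float)
    var = float(g @ cov @ g) + float(count_variance)
    from scipy import stats

    zq = stats.norm.ppf(0.5 + level / 2)
    half = zq * np.sqrt(max(var, 0.0))
    return point - half, point + half


def forecast(fit: GEEFit, roster: pd.DataFrame, lms: gr.LMSReference,
             incidence: IncidenceRates, population: PopulationProjection,
             group_covs: pd.DataFrame, mortality: MortalityModel,
             horizon: list[int], base_year: int,
             scenario: str = "baseline") -> pd.DataFrame:
    """One scenario's forecast table: per year, expected existing / new-case /
    total units with 95% delta-method prediction intervals."""
    horizon = list(horizon)
    ex_units, ex_grad = project_existing(fit, roster, lms, mortality, horizon, base_year)
    new_units, new_grad, cvar = project_new_cases(
        fit, incidence, population, group_covs, lms, mortality, horizon, base_year
    )
    rows = []
    cov = fit.robust_cov.to_numpy()
    for year in horizon:
        total = float(ex_units[year] + new_units[year])
        g = ex_grad.loc[year].to_numpy() + new_grad.loc[year].to_numpy()
        lo, hi = delta_method_pi(total, g, cov, float(cvar[year]))
        rows.append({
            "scenario": scenario,
            "year": year,
            "existing_units": float(ex_units[year]),
            "newcase_units": float(new_units[year]),
            "total_units": total,
            "pi_lo": lo,
            "pi_hi": hi,
        })
    return pd.DataFrame(rows)


def run_scenarios(fit: GEEFit, roster: pd.DataFrame, lms: gr.LMSReference,
                  incidence: IncidenceRates, population: PopulationProjection,
                  group_covs: pd.DataFrame, adult_mortality: float,
                  horizon: list[int], base_year: int,
                  reductions: dict | None = None) -> pd.DataFrame:
    """Baseline plus mortality-reduction sensitivity scenarios (by default a
    further 40% and 80% linear reduction over 10 years, adults only)."""
    if reductions is None:
        reductions = {"baseline": 0.0, "mort-40": 0.4, "mort-80": 0.8}
    frames = []
    for name, r in reductions.items():
        mort = MortalityModel(adult_mortality, reduction=r)
        frames.append(
            forecast(fit, roster, lms, incidence, population, group_covs,
                     mort, horizon, base_year, scenario=name)
        )
    return pd.concat(frames, ignore_index=True)


def growth_summary(values, start_year: int, end_year: int):
    """Total percent change and annualized growth rate between two years.

    ``values`` may be a forecast DataFrame (uses ``total_units``), a mapping
    year -> total, or a Series indexed by year.
    """
    if isinstance(values, pd.DataFrame):
        series = values.set_index("year")["total_units"]
    elif isinstance(values, pd.Series):
        series = values
    else:
        series = pd.Series(dict(values))
    start, end = float(series[start_year]), float(series[end_year])
    if start == 0:
        raise ValueError("start value is zero; growth undefined")
    span = end_year - start_year
    pct = (end - start) / start * 100.0
    annualized = ((end / start) ** (1.0 / span) - 1.0) * 100.0
    return pct, annualized
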