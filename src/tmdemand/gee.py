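"""Poisson GEE demand model: log link, independent/exchangeable working
correlation, Pearson scale, and robust (sandwich) covariance.

The marginal model is E[units] = exp(x'beta) with within-patient correlation
handled by generalized estimating equations (Liang-Zeger). exp(beta) is the
relative blood demand per unit covariate change; the sandwich covariance is
valid under working-correlation misspecification.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Predictors present in every model variant.
BASE_TERMS = ("age", "weight", "female", "splenectomy")

#: Quadratic term -> its required linear parent.
QUADRATIC_PARENT = {"age2": "age", "weight2": "weight"}

_TERM_ORDER = (
    "age", "age2", "weight", "weight2", "female", "splenectomy",
    "year_of_transfusion",
)


class ConvergenceError(RuntimeError):
    """GEE iterations did not converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class DegenerateOutcomeError(ValueError):
    """Outcome cannot identify the model (e.g. all zeros)."""


@dataclass(frozen=True)
class ModelVariant:
    """A predictor set plus a working correlation structure.

    ``extra_terms`` extends the always-included base predictors (age, weight,
    female, splenectomy). Quadratic terms require their linear parent;
    interaction terms are written ``"a:b"``.
    """

    extra_terms: tuple = ()
    working_correlation: str = "independent"

    def __post_init__(self):
        if self.working_correlation not in ("independent", "exchangeable"):
            raise ValueError(
                f"unknown working correlation {self.working_correlation!r}"
            )
        terms = self.terms
        for quad, lin in QUADRATIC_PARENT.items():
            if quad in terms and lin not in terms:
                raise ValueError(f"{quad} requires the linear term {lin}")
        for t in self.extra_terms:
            for part in t.split(":"):
                if part not in _TERM_ORDER:
                    raise ValueError(f"unknown term {part!r}")

    @property
    def terms(self) -> tuple:
        """Ordered, de-duplicated predictor names (no intercept)."""
        seen = list(BASE_TERMS)
        for t in self.extra_terms:
            if t not in seen:
                seen.append(t)
        mains = [t for t in _TERM_ORDER if t in seen]
        inters = [t for t in seen if ":" in t]
        return tuple(mains + inters)

    @property
    def n_predictors(self) -> int:
        return len(self.terms)

    @property
    def name(self) -> str:
        extras = [t for t in self.terms if t not in BASE_TERMS]
        label = "base" if not extras else "base+" + "+".join(extras)
        return f"{label}|{self.working_correlation}"

    def __str__(self) -> str:
        return self.name


def default_grid() -> list[ModelVariant]:
    """The 16-cell comparison grid: 8 predictor sets x 2 working correlations."""
    extra_sets = [
        (),
        ("age2",),
        ("weight2",),
        ("year_of_transfusion",),
        ("age2", "weight2"),
        ("age2", "year_of_transfusion"),
        ("weight2", "year_of_transfusion"),
        ("age2", "weight2", "year_of_transfusion"),
    ]
    return [
        ModelVariant(extras, corr)
        for extras in extra_sets
        for corr in ("independent", "exchangeable")
    ]


def interaction_grid() -> list[ModelVariant]:
    """Variants adding pairwise interactions of {age, weight} x {female, splenectomy}
    on top of the quadratic model, independent correlation."""
    inters = ["age:female", "age:splenectomy", "weight:female", "weight:splenectomy"]
    out = []
    for inter in inters:
        out.append(ModelVariant(("age2", "weight2", inter), "independent"))
    out.append(ModelVariant(("age2", "weight2", *inters), "independent"))
    return out


# ---------------------------------------------------------------------------
# Covariate construction


def _covariate_frame(panel: pd.DataFrame) -> pd.DataFrame:
    """Base covariates from a panel; derives female from sex and
    year_of_transfusion as years since each patient's first recorded year."""
    cov = pd.DataFrame(index=panel.index)
    cov["age"] = panel["age_years"].astype(float)
    cov["weight"] = panel["weight_kg"].astype(float)
    if "female" in panel.columns:
        cov["female"] = panel["female"].astype(float)
    else:
        cov["female"] = (panel["sex"].astype(str).str.upper() == "F").astype(float)
    cov["splenectomy"] = panel["splenectomy"].astype(float)
    first = panel.groupby("patient_id")["year"].transform("min")
    cov["year_of_transfusion"] = (panel["year"] - first).astype(float)
    return cov


def term_values(cov: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate one model term (main, quadratic, or ':' interaction) on
    uncentred covariates."""
    if term == "age2":
        return cov["age"].to_numpy() ** 2
    if term == "weight2":
        return cov["weight"].to_numpy() ** 2
    if ":" in term:
        a, b = term.split(":")
        return term_values(cov, a) * term_values(cov, b)
    return cov[term].to_numpy(dtype=float)


def build_design(panel: pd.DataFrame, variant: ModelVariant):
    """Design matrix (intercept first), outcome, and patient ids for a variant.

    Quadratic terms use uncentred age/weight so exp(beta) reads as the
    per-year / per-kg relative demand at the natural origin.
    """
    cov = _covariate_frame(panel)
    cols = {"const": np.ones(len(panel))}
    for term in variant.terms:
        cols[term] = term_values(cov, term)
    X = pd.DataFrame(cols, index=panel.index)
    y = panel["units"].to_numpy(dtype=float)
    groups = panel["patient_id"].to_numpy()
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            rest = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                bad.append(name)
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    return X, y, groups


def variance_inflation(X: pd.DataFrame) -> pd.Series:
    """VIF of each non-intercept column (reported, not enforced)."""
    cols = [c for c in X.columns if c != "const"]
    Z = X[cols].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=0)
    corr = (Z.T @ Z) / len(Z)
    vif = np.diag(np.linalg.inv(corr))
    return pd.Series(vif, index=cols, name="vif")


# ---------------------------------------------------------------------------
# Exclusion filters


@dataclass
class ExclusionLog:
    """Per-reason tallies of what the filters removed."""

    irregular_patients: list = field(default_factory=list)
    missing_weight_patients: list = field(default_factory=list)
    infant_rows: int = 0

    def summary(self) -> dict:
        return {
            "irregular_patients": len(self.irregular_patients),
            "missing_weight_patients": len(self.missing_weight_patients),
            "infant_rows_dropped": self.infant_rows,
        }


def apply_exclusions(panel: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the cohort filters before model fitting.

    Removes, in order: patient-years at age < 1 (transfusion therapy starts
    at 6-12 months, so infant rows are unreliable); patients with a
    zero-demand or missing year strictly inside their observation span
    (irregular transfusion); patients with no recorded weight in any year.
    """
    log = ExclusionLog()
    panel = panel.copy()

    infants = panel["age_years"] < 1
    log.infant_rows = int(infants.sum())
    panel = panel.loc[~infants]

    for pid, sub in panel.groupby("patient_id", sort=False):
        years = sub["year"].to_numpy()
        units = sub["units"].to_numpy(dtype=float)
        span = np.arange(years.min(), years.max() + 1)
        if len(span) <= 1:
            continue
        present = {int(y): u for y, u in zip(years, units)}
        if any(present.get(int(y), 0.0) <= 0 for y in span):
            log.irregular_patients.append(pid)
    if log.irregular_patients:
        panel = panel.loc[~panel["patient_id"].isin(log.irregular_patients)]

    if "weight_kg" in panel.columns:
        w = pd.to_numeric(panel["weight_kg"], errors="coerce")
        has_weight = w.gt(0).groupby(panel["patient_id"]).any()
        missing = has_weight.index[~has_weight].tolist()
        if missing:
            log.missing_weight_patients = missing
            panel = panel.loc[~panel["patient_id"].isin(missing)]

    return panel.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class GEEFit:
    """Everything prediction and delta-method intervals need."""

    params: pd.Series
    robust_cov: pd.DataFrame
    scale: float
    working_correlation: str
    alpha: float | None
    n_patients: int
    n_obs: int

    @property
    def terms(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]

    def design_row(self, covariates: dict) -> np.ndarray:
        """Design vector for one covariate setting, in fitted column order."""
        cov = pd.DataFrame({k: [float(v)] for k, v in covariates.items()})
        row = []
        for name in self.params.index:
            if name == "const":
                row.append(1.0)
            else:
                row.append(float(term_values(cov, name)[0]))
        return np.array(row)

    def predict(self, covariates: dict) -> float:
        """Expected units/year at one covariate setting: exp(x'beta)."""
        missing = set()
        for name in self.params.index:
            if name == "const":
                continue
            for part in name.split(":"):
                base = QUADRATIC_PARENT.get(part, part)
                if base not in covariates:
                    missing.add(base)
        if missing:
            raise ValueError(f"missing covariates for prediction: {sorted(missing)}")
        return float(np.exp(self.design_row(covariates) @ self.params.to_numpy()))

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "robust_cov": self.robust_cov.to_numpy().tolist(),
            "param_order": list(self.params.index),
            "scale": self.scale,
            "working_correlation": self.working_correlation,
            "alpha": self.alpha,
            "n_patients": self.n_patients,
            "n_obs": self.n_obs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GEEFit":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        order = payload["param_order"]
        return cls(
            params=pd.Series({k: payload["params"][k] for k in order}),
            robust_cov=pd.DataFrame(
                payload["robust_cov"], index=order, columns=order
            ),
            scale=payload["scale"],
            working_correlation=payload["working_correlation"],
            alpha=payload["alpha"],
            n_patients=payload["n_patients"],
            n_obs=payload["n_obs"],
        )


def fit_gee(X, y, groups, working_correlation: str = "independent",
            maxiter: int = 100) -> GEEFit:
    """Fit the Poisson GEE and return coefficients, sandwich covariance,
    Pearson scale and (for exchangeable) the correlation estimate.

    Independent working correlation solves the pooled Poisson score
    equations; iterations start at the Poisson maximum-likelihood solution
    so the root agrees with plain IRLS to solver precision.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 patients to fit a GEE")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise DegenerateOutcomeError("outcome must be non-negative integers")
    if np.all(y == 0):
        raise DegenerateOutcomeError("outcome is identically zero")

    fam = sm.families.Poisson()
    glm_start = sm.GLM(y, X, family=fam).fit().params.to_numpy()
    if working_correlation == "independent":
        cov_struct = sm.cov_struct.Independence()
    elif working_correlation == "exchangeable":
        cov_struct = sm.cov_struct.Exchangeable()
    else:
        raise ValueError(f"unknown working correlation {working_correlation!r}")

    model = sm.GEE(y, X, groups=groups, family=fam, cov_struct=cov_struct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=maxiter, ctol=1e-10, start_params=glm_start)
    # statsmodels' ctol tests the score norm, whose numerical floor scales
    # with the data; judge convergence by the relative coefficient change
    trace = res.fit_history.get("params", [])
    if len(trace) >= maxiter:
        last, prev = trace[-1], trace[-2]
        rel = np.max(np.abs(last - prev) / (np.abs(last) + 1e-10))
        if rel > 1e-8:
            raise ConvergenceError(
                f"GEE did not converge in {maxiter} iterations "
                f"(last relative change {rel:.2e})", trace=trace
            )

    beta = pd.Series(np.asarray(res.params, dtype=float), index=X.columns)
    mu = np.exp(X.to_numpy() @ beta.to_numpy())
    pearson = (y - mu) / np.sqrt(mu)
    dof = len(y) - X.shape[1]
    scale = float(pearson @ pearson / dof)
    cov = pd.DataFrame(
        np.asarray(res.cov_robust, dtype=float), index=X.columns, columns=X.columns
    )
    eig = np.linalg.eigvalsh(cov.to_numpy())
    if eig.min() < -1e-10:
        raise ValueError("robust covariance is not positive semi-definite")
    alpha = None
    if working_correlation == "exchangeable":
        alpha = float(np.atleast_1d(cov_struct.dep_params)[0])
    return GEEFit(
        params=beta,
        robust_cov=cov,
        scale=scale,
        working_correlation=working_correlation,
        alpha=alpha,
        n_patients=len(np.unique(groups)),
        n_obs=len(y),
    )


def fit_model(panel: pd.DataFrame, variant: ModelVariant) -> GEEFit:
    """Convenience wrapper: build the variant's design and fit it."""
    X, y, groups = build_design(panel, variant)
    return fit_gee(X, y, groups, variant.working_correlation)


# ---------------------------------------------------------------------------
# Fast beta-only solver (used for cross-validation fold refits)


def group_starts(groups_sorted: np.ndarray) -> np.ndarray:
    """reduceat boundaries for an array already sorted by group."""
    n = len(groups_sorted)
    if n == 0:
        return np.array([], dtype=int)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = groups_sorted[1:] != groups_sorted[:-1]
    return np.flatnonzero(change)


def solve_beta(X: np.ndarray, y: np.ndarray, groups_sorted: np.ndarray,
               working_correlation: str, start: np.ndarray,
               tol: float = 1e-10, maxiter: int = 100) -> np.ndarray:
    """Fisher-scoring root of the Poisson GEE estimating equations.

    Rows must be sorted by patient. Exchangeable correlation re-estimates
    the moment alpha each iteration; its block inverse is applied in closed
    form, so a fold refit warm-started at the full-data solution costs a
    couple of cheap iterations. Returns beta only (no covariance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.asarray(start, dtype=float).copy()
    starts = group_starts(groups_sorted)
    sizes = np.diff(np.append(starts, n))
    exch = working_correlation == "exchangeable"
    pair_count = float(np.sum(sizes * (sizes - 1) / 2))

    def parts(b, alpha=None):
        """(score, Xs, Xr, er, alpha) at b; alpha re-estimated unless given."""
        eta = X @ b
        if np.max(eta) > 50:
            return None
        mu = np.exp(eta)
        sqmu = np.sqrt(mu)
        e = (y - mu) / sqmu
        Xs = X * sqmu[:, None]
        if exch and pair_count > p:
            if alpha is None:
                phi = float(e @ e) / max(n - p, 1)
                r = e / np.sqrt(phi)
                gsum_r = np.add.reduceat(r, starts)
                gsum_r2 = np.add.reduceat(r * r, starts)
                alpha = float(((gsum_r**2 - gsum_r2) / 2).sum() / (pair_count - p))
                alpha = float(np.clip(alpha, -0.95, 0.95))
            c = alpha / (1.0 + (sizes - 1) * alpha)  # per group
            c_row = np.repeat(c, sizes)
            sum_e = np.repeat(np.add.reduceat(e, starts), sizes)
            sum_X = np.repeat(np.add.reduceat(Xs, starts, axis=0), sizes, axis=0)
            er = (e - c_row * sum_e) / (1.0 - alpha)
            Xr = (Xs - c_row[:, None] * sum_X) / (1.0 - alpha)
        else:
            er, Xr, alpha = e, Xs, 0.0
        return Xs.T @ er, Xs, Xr, er, alpha

    cur = parts(beta)
    if cur is None:
        raise ValueError("starting values give an unbounded linear predictor")
    for _ in range(maxiter):
        score, Xs, Xr, er, alpha = cur
        # R^-1 is symmetric: Xs' R^-1 e = Xs' er and Xs' R^-1 Xs = Xs' Xr
        H = Xs.T @ Xr
        delta = np.linalg.solve(H, score)
        # step-halving on divergence of the estimating-function norm
        # (alpha frozen while judging the step)
        norm0 = float(score @ score)
        step = 1.0
        while step > 1e-8:
            cand = parts(beta + step * delta, alpha=alpha if exch else None)
            if cand is not None and float(cand[0] @ cand[0]) <= norm0 * (1 + 1e-8):
                break
            step /= 2
        beta = beta + step * delta
        cur = cand if (cand is not None and not exch) else parts(beta)
        if np.max(np.abs(step * delta) / (np.abs(beta) + 1e-10)) <= tol:
            return beta
    raise ConvergenceError(f"solve_beta did not converge in {maxiter} iterations")


# ---------------------------------------------------------------------------
# Reporting


def relative_demand_table(fit: GEEFit) -> pd.DataFrame:
    """Relative blood demand exp(beta) with robust Wald 95% CIs and p-values,
    one row per non-intercept term."""
    rows = []
    for term in fit.terms:
        b = fit.params[term]
        se = float(np.sqrt(fit.robust_cov.loc[term, term]))
        z = b / se if se > 0 else np.inf
        p = 2 * stats.norm.sf(abs(z))
        rows.append({
            "term": term,
            "rr": np.exp(b),
            "ci_lo": np.exp(b - 1.96 * se),
            "ci_hi": np.exp(b + 1.96 * se),
            "p": p,
        })
    return pd.DataFrame(rows)


def peak_covariate(fit: GEEFit, term: str) -> float:
    """Covariate value maximizing demand under a quadratic effect:
    argmax of b1*x + b2*x^2 is -b1/(2*b2), requiring b2 < 0."""
    quad = f"{term}2"
    if quad not in fit.params.index:
        raise ValueError(f"fit has no quadratic term for {term!r}")
    b1, b2 = float(fit.params[term]), float(fit.params[quad])
    if b2 >= 0:
        raise ValueError(f"no interior maximum: coefficient on {quad} is >= 0")
    return -b1 / (2.0 * b2)


def predict_mean(fit: GEEFit, covariates: dict) -> float:
    """Expected units/year at a covariate setting (alias of GEEFit.predict)."""
    return fit.predict(covariates)
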