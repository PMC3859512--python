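import numpy as np
import pandas as pd
import pytest

from tmdemand import synthetic_data as sd
from tmdemand import gee, growth


@pytest.fixture(scope="session")
def lms():
    return sd.generate_lms_reference()


@pytest.fixture(scope="session")
def small_cohort(lms):
    """A reduced but otherwise default-condition cohort (fast fixture)."""
    cfg = sd.GeneratorConfig(n_patients=80, seed=7)
    return sd.generate_cohort(cfg, lms)


@pytest.fixture(scope="session")
def clean_panel(small_cohort, lms):
    panel, _ = gee.apply_exclusions(small_cohort.panel)
    panel, _ = growth.backfill_weights(panel, lms)
    return panel


def make_panel(rows):
    """Hand-built panel from (patient_id, year, sex, age, weight, splen, units)."""
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "year", "sex", "age_years", "weight_kg",
                 "splenectomy", "units"],
    )
    df["death_year"] = pd.array([pd.NA] * len(df), dtype="Int64")
    return df


def poisson_newton(X, y, tol=1e-12, maxiter=200):
    """Independent oracle: damped Newton on the Poisson log-likelihood."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-3))

    def loglik(b):
        eta = X @ b
        return float(y @ eta - np.exp(eta).sum())

    ll = loglik(beta)
    for _ in range(maxiter):
        mu = np.exp(X @ beta)
        score = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, score)
        scale = 1.0
        while scale > 1e-8:
            cand = beta + scale * step
            if loglik(cand) >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        ll = loglik(beta)
        if np.max(np.abs(scale * step)) < tol:
            break
    return beta
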