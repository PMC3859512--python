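"""Poisson GEE estimation: oracle equivalence, exclusion filters, sandwich
properties, and effect reporting."""
import math

import numpy as np
import pandas as pd
import pytest

from tmdemand import gee, growth
from tmdemand import synthetic_data as sd
from tmdemand.gee import (
    GEEFit, ModelVariant, apply_exclusions, build_design, default_grid,
    fit_gee, fit_model, peak_covariate, predict_mean, relative_demand_table,
    solve_beta, variance_inflation,
)
from .conftest import make_panel, poisson_newton


class TestModelVariant:
    def test_base_variant_design_has_five_columns(self, clean_panel):
        X, y, groups = build_design(clean_panel, ModelVariant())
        assert list(X.columns) == ["const", "age", "weight", "female", "splenectomy"]

    def test_full_variant_has_eight_columns(self, clean_panel):
        v = ModelVariant(("age2", "weight2", "year_of_transfusion"))
        X, _, _ = build_design(clean_panel, v)
        assert X.shape[1] == 8

    def test_quadratic_requires_linear_parent(self):
        # base terms always present, so age2 alone is fine; an unknown
        # parentless quadratic is not expressible
        v = ModelVariant(("age2",))
        assert "age" in v.terms

    def test_rejects_unknown_terms(self):
        with pytest.raises(ValueError, match="unknown term"):
            ModelVariant(("bmi",))

    def test_default_grid_is_sixteen_cells(self):
        grid = default_grid()
        assert len(grid) == 16
        assert len({v.name for v in grid}) == 16

    def test_collinear_design_rejected(self, clean_panel):
        panel = clean_panel.copy()
        panel["weight_kg"] = panel["age_years"] * 2.0  # weight == 2*age
        with pytest.raises(ValueError, match="collinear"):
            build_design(panel, ModelVariant())

    def test_vif_reported_per_predictor(self, clean_panel):
        """VIFs are reported (not enforced) for every non-intercept term;
        indicator covariates are near-orthogonal to the rest."""
        X, _, _ = build_design(clean_panel, ModelVariant())
        vif = variance_inflation(X)
        assert list(vif.index) == ["age", "weight", "female", "splenectomy"]
        assert (vif >= 1).all()
        # sex and splenectomy are assigned independently of age/weight
        assert vif[["female", "splenectomy"]].lt(2).all()


class TestExclusions:
    def test_clean_cohort_passes_untouched(self, lms):
        cfg = sd.GeneratorConfig(
            n_patients=40, seed=3, frac_irregular=0.0,
            frac_missing_all_weight=0.0, frac_missing_weight_row=0.0,
            incidence_per_100k=0.0, mortality_rate_adult=0.0,
        )
        panel = sd.generate_cohort(cfg, lms).panel
        out, log = apply_exclusions(panel)
        assert log.summary() == {
            "irregular_patients": 0,
            "missing_weight_patients": 0,
            "infant_rows_dropped": 0,
        }
        assert len(out) == len(panel)

    def test_gap_year_marks_patient_irregular(self):
        panel = make_panel([
            ("a", 2005, "M", 20, 60.0, 0, 40),
            ("a", 2006, "M", 21, 60.0, 0, 0),
            ("a", 2007, "M", 22, 60.0, 0, 41),
            ("b", 2005, "M", 20, 60.0, 0, 38),
            ("b", 2006, "M", 21, 60.0, 0, 39),
        ])
        out, log = apply_exclusions(panel)
        assert log.irregular_patients == ["a"]
        assert set(out["patient_id"]) == {"b"}

    def test_missing_year_also_counts_as_gap(self):
        panel = make_panel([
            ("a", 2005, "M", 20, 60.0, 0, 40),
            ("a", 2007, "M", 22, 60.0, 0, 41),
        ])
        _, log = apply_exclusions(panel)
        assert log.irregular_patients == ["a"]

    def test_infant_rows_dropped_patient_kept(self):
        panel = make_panel([
            ("a", 2005, "F", 0, 5.0, 0, 3),
            ("a", 2006, "F", 1, 9.0, 0, 12),
            ("a", 2007, "F", 2, 12.0, 0, 15),
        ])
        out, log = apply_exclusions(panel)
        assert log.infant_rows == 1
        assert set(out["patient_id"]) == {"a"}
        assert (out["age_years"] >= 1).all()

    def test_no_weight_patient_excluded(self):
        panel = make_panel([
            ("a", 2005, "M", 20, np.nan, 0, 40),
            ("a", 2006, "M", 21, np.nan, 0, 41),
            ("b", 2005, "M", 20, 60.0, 0, 38),
            ("b", 2006, "M", 21, 61.0, 0, 37),
        ])
        out, log = apply_exclusions(panel)
        assert log.missing_weight_patients == ["a"]


class TestFitGEE:
    def test_constant_outcome_intercept_closed_form(self):
        X = pd.DataFrame({"const": np.ones(10)})
        y = np.full(10, 7.0)
        groups = np.repeat(np.arange(5), 2)
        for corr in ("independent", "exchangeable"):
            fit = fit_gee(X, y, groups, corr)
            assert fit.params["const"] == pytest.approx(math.log(7.0), abs=1e-8)

    def test_independent_gee_equals_poisson_ml(self, clean_panel):
        """One observation per patient: the GEE root is the Poisson MLE
        computed by an independent Newton solver."""
        panel = clean_panel.groupby("patient_id").head(1).head(200)
        X, y, groups = build_design(panel, ModelVariant(("age2", "weight2")))
        fit = fit_gee(X, y, groups, "independent")
        oracle = poisson_newton(X.to_numpy(), y)
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-8)

    def test_all_zero_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(6)})
        y = np.zeros(6)
        with pytest.raises(gee.DegenerateOutcomeError):
            fit_gee(X, y, np.arange(6))

    def test_single_patient_rejected(self):
        X = pd.DataFrame({"const": np.ones(4)})
        with pytest.raises(ValueError, match="2 patients"):
            fit_gee(X, np.ones(4), np.zeros(4))

    def test_scale_matches_pearson_formula(self, clean_panel):
        fit = fit_model(clean_panel, ModelVariant(("age2", "weight2")))
        X, y, _ = build_design(clean_panel, ModelVariant(("age2", "weight2")))
        mu = np.exp(X.to_numpy() @ fit.params.to_numpy())
        phi = float(((y - mu) ** 2 / mu).sum() / (len(y) - X.shape[1]))
        assert fit.scale == pytest.approx(phi, rel=1e-12)

    def test_sandwich_ses_do_not_depend_on_scale(self, clean_panel):
        """The Pearson scale cancels in B^-1 M B^-1: robust SEs from the
        scale-free sandwich match statsmodels' to numerical precision."""
        import statsmodels.api as sm

        X, y, groups = build_design(clean_panel, ModelVariant())
        fit = fit_gee(X, y, groups, "independent")
        # hand-built sandwich with phi forced to 1
        beta = fit.params.to_numpy()
        mu = np.exp(X.to_numpy() @ beta)
        B = X.to_numpy().T @ (X.to_numpy() * mu[:, None])
        M = np.zeros_like(B)
        for pid in np.unique(groups):
            m = groups == pid
            s = X.to_numpy()[m].T @ (y[m] - mu[m])
            M += np.outer(s, s)
        Binv = np.linalg.inv(B)
        sandwich = Binv @ M @ Binv
        np.testing.assert_allclose(
            np.sqrt(np.diag(sandwich)),
            np.sqrt(np.diag(fit.robust_cov.to_numpy())),
            rtol=1e-6,
        )

    def test_exchangeable_alpha_near_zero_without_correlation(self, lms):
        cfg = sd.GeneratorConfig(
            n_patients=2200, seed=9, within_corr=0.0, scale=1.7,
            frac_irregular=0.0, frac_missing_all_weight=0.0,
            frac_missing_weight_row=0.0, incidence_per_100k=0.0,
        )
        panel = sd.generate_cohort(cfg, lms).panel
        assert len(panel) >= 10_000
        # mean must be correctly specified: omitted quadratic structure would
        # masquerade as within-patient correlation
        fit = fit_model(panel, ModelVariant(("age2", "weight2"), "exchangeable"))
        assert abs(fit.alpha) <= 0.05

    def test_exchangeable_alpha_positive_with_frailty(self, clean_panel):
        fit = fit_model(clean_panel, ModelVariant(("age2", "weight2"), "exchangeable"))
        assert fit.alpha > 0.05


class TestSolveBeta:
    """The fast fold-refit solver must sit on the same root as statsmodels."""

    @pytest.mark.parametrize("corr", ["independent", "exchangeable"])
    def test_matches_statsmodels_root(self, clean_panel, corr):
        X, y, groups = build_design(clean_panel, ModelVariant(("age2", "weight2")))
        order = np.argsort(groups, kind="stable")
        start = np.zeros(X.shape[1])
        start[0] = np.log(y.mean())
        beta = solve_beta(X.to_numpy()[order], y[order],
                          np.asarray(groups)[order], corr, start)
        fit = fit_gee(X, y, groups, corr)
        np.testing.assert_allclose(beta, fit.params.to_numpy(), atol=1e-8)

    def test_warm_start_invariance(self, clean_panel):
        X, y, groups = build_design(clean_panel, ModelVariant(("age2",)))
        order = np.argsort(groups, kind="stable")
        Xa, ya, ga = X.to_numpy()[order], y[order], np.asarray(groups)[order]
        cold = np.zeros(X.shape[1])
        cold[0] = np.log(y.mean())
        b_cold = solve_beta(Xa, ya, ga, "independent", cold)
        b_warm = solve_beta(Xa, ya, ga, "independent", b_cold * 1.02)
        np.testing.assert_allclose(b_cold, b_warm, atol=1e-8)


class TestReporting:
    def test_rr_table_transform(self):
        """A coefficient ln(0.85) with robust SE 0.024 reports RR 0.85 with
        CI about (0.81, 0.89), the Wald transform on the log scale."""
        params = pd.Series({"const": 3.0, "splenectomy": math.log(0.85)})
        cov = pd.DataFrame(
            np.diag([0.01, 0.024**2]),
            index=params.index, columns=params.index,
        )
        fit = GEEFit(params, cov, 1.7, "independent", None, 100, 400)
        row = relative_demand_table(fit).set_index("term").loc["splenectomy"]
        assert row["rr"] == pytest.approx(0.85)
        assert row["ci_lo"] == pytest.approx(0.81, abs=0.005)
        assert row["ci_hi"] == pytest.approx(0.89, abs=0.005)
        assert row["p"] < 0.001

    def test_null_coefficient_gives_rr_one(self):
        params = pd.Series({"const": 3.0, "female": 0.0})
        cov = pd.DataFrame(np.diag([0.01, 0.04]), index=params.index,
                           columns=params.index)
        fit = GEEFit(params, cov, 1.0, "independent", None, 10, 40)
        row = relative_demand_table(fit).set_index("term").loc["female"]
        assert row["rr"] == 1.0
        assert row["ci_lo"] < 1.0 < row["ci_hi"]

    def test_ci_width_shrinks_with_sample_size(self, lms):
        widths = []
        for n in (60, 240, 960):
            cfg = sd.GeneratorConfig(
                n_patients=n, seed=13, frac_irregular=0.0,
                frac_missing_all_weight=0.0, frac_missing_weight_row=0.0,
                incidence_per_100k=0.0,
            )
            panel = sd.generate_cohort(cfg, lms).panel
            fit = fit_model(panel, ModelVariant())
            t = relative_demand_table(fit).set_index("term")
            widths.append(t.loc["female", "ci_hi"] - t.loc["female", "ci_lo"])
        assert widths[0] > widths[1] > widths[2]

    def test_peak_covariate_closed_form(self):
        params = pd.Series({"const": 2.0, "age": 0.04, "age2": -0.0008})
        cov = pd.DataFrame(np.eye(3) * 1e-4, index=params.index,
                           columns=params.index)
        fit = GEEFit(params, cov, 1.0, "independent", None, 10, 40)
        assert peak_covariate(fit, "age") == pytest.approx(25.0)

    def test_peak_zero_linear_term(self):
        params = pd.Series({"const": 2.0, "age": 0.0, "age2": -0.0008})
        cov = pd.DataFrame(np.eye(3), index=params.index, columns=params.index)
        fit = GEEFit(params, cov, 1.0, "independent", None, 10, 40)
        assert peak_covariate(fit, "age") == 0.0

    def test_peak_requires_concavity(self):
        params = pd.Series({"const": 2.0, "age": 0.04, "age2": 0.0008})
        cov = pd.DataFrame(np.eye(3), index=params.index, columns=params.index)
        fit = GEEFit(params, cov, 1.0, "independent", None, 10, 40)
        with pytest.raises(ValueError, match="maximum"):
            peak_covariate(fit, "age")


class TestPrediction:
    def test_intercept_only_mean(self):
        params = pd.Series({"const": math.log(40.0)})
        cov = pd.DataFrame([[0.01]], index=["const"], columns=["const"])
        fit = GEEFit(params, cov, 1.0, "independent", None, 5, 20)
        assert fit.predict({}) == pytest.approx(40.0)

    def test_log_two_coefficient_doubles_mean(self):
        params = pd.Series({"const": math.log(40.0), "splenectomy": math.log(2.0)})
        cov = pd.DataFrame(np.eye(2), index=params.index, columns=params.index)
        fit = GEEFit(params, cov, 1.0, "independent", None, 5, 20)
        m0 = fit.predict({"splenectomy": 0})
        m1 = fit.predict({"splenectomy": 1})
        assert m1 == pytest.approx(2 * m0)

    def test_missing_covariate_raises(self):
        params = pd.Series({"const": 1.0, "age": 0.02, "age2": -0.001})
        cov = pd.DataFrame(np.eye(3), index=params.index, columns=params.index)
        fit = GEEFit(params, cov, 1.0, "independent", None, 5, 20)
        with pytest.raises(ValueError, match="age"):
            fit.predict({"weight": 50})

    def test_training_predictions_average_to_observed_mean(self, clean_panel):
        """With an intercept and independent working correlation the score
        equation forces sum(mu_hat) = sum(y)."""
        X, y, groups = build_design(clean_panel, ModelVariant(("age2", "weight2")))
        fit = fit_gee(X, y, groups, "independent")
        mu = np.exp(X.to_numpy() @ fit.params.to_numpy())
        assert mu.mean() == pytest.approx(y.mean(), rel=1e-6)

    def test_fit_json_round_trip(self, clean_panel, tmp_path):
        fit = fit_model(clean_panel, ModelVariant(("age2",), "exchangeable"))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = GEEFit.from_json(path)
        pd.testing.assert_series_equal(fit.params, back.params)
        assert back.alpha == fit.alpha
        assert back.predict({"age": 20, "weight": 55, "female": 1,
                             "splenectomy": 0}) == pytest.approx(
            fit.predict({"age": 20, "weight": 55, "female": 1, "splenectomy": 0})
        )


class TestParameterRecovery:
    def test_estimates_within_three_robust_ses(self, lms):
        """Point recovery of the generating coefficients on one cohort."""
        cfg = sd.GeneratorConfig(
            n_patients=400, seed=21, frac_irregular=0.0,
            frac_missing_all_weight=0.0, frac_missing_weight_row=0.0,
            incidence_per_100k=0.0,
        )
        panel = sd.generate_cohort(cfg, lms).panel
        fit = fit_model(panel, ModelVariant(("age2", "weight2")))
        truth = cfg.beta
        for term in ("age", "age2", "weight", "weight2", "female", "splenectomy"):
            se = math.sqrt(fit.robust_cov.loc[term, term])
            assert abs(fit.params[term] - truth[term]) < 3 * se, term

    def test_robust_wald_coverage(self, lms):
        """Nominal 95% robust intervals cover the generating female effect in
        >= 90% of 200 scaled-down replicates (120 patients keeps the sandwich
        out of its small-cluster-count bias regime)."""
        truth = math.log(0.94)
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = sd.GeneratorConfig(
                n_patients=120, years=(2005, 2007), seed=100_000 + seed,
                frac_irregular=0.0, frac_missing_all_weight=0.0,
                frac_missing_weight_row=0.0, incidence_per_100k=0.0,
                mortality_rate_adult=0.0,
            )
            panel = sd.generate_cohort(cfg, lms).panel
            fit = fit_model(panel, ModelVariant(("age2", "weight2")))
            se = math.sqrt(fit.robust_cov.loc["female", "female"])
            if abs(fit.params["female"] - truth) <= 1.96 * se:
                hits += 1
        assert hits / n_rep >= 0.90
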