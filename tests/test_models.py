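import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit

from streetcover.errors import InvalidInputError, RankDeficiencyError, SeparationError
from streetcover.glmm import _LaplaceObjective, fit_logistic_glmm
from streetcover.models import (
    build_availability_design,
    build_subcity_design,
    fit_availability_model,
    fit_subcity_model,
    pool_central_america,
    run_model_battery,
    standardize_xy,
)
from streetcover.pipeline import run_full_analysis, run_study_pipeline
from streetcover.simulate import draw_point_outcomes


class TestStandardizeXY:
    def test_three_point_line(self):
        frame = pd.DataFrame({"city_id": "c", "x": [0.0, 500.0, 1000.0], "y": [0.0, 0.0, 1.0]})
        out = standardize_xy(frame)
        assert out["x_std"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one_per_city_per_axis(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "city_id": np.repeat(["a", "b"], 40),
                "x": rng.uniform(0, 5000, 80),
                "y": rng.uniform(0, 5000, 80),
            }
        )
        out = standardize_xy(frame)
        for _, grp in out.groupby("city_id"):
            for col in ("x_std", "y_std"):
                assert grp[col].mean() == pytest.approx(0.0, abs=1e-12)
                assert grp[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            {"city_id": "a", "x": rng.uniform(0, 100, 30), "y": rng.uniform(0, 100, 30)}
        )
        moved = frame.assign(x=frame["x"] + 1234.5, y=frame["y"] - 999.9)
        a, b = standardize_xy(frame), standardize_xy(moved)
        assert np.allclose(a[["x_std", "y_std"]], b[["x_std", "y_std"]])

    def test_single_point_city_warns_zero(self):
        frame = pd.DataFrame({"city_id": ["a"], "x": [5.0], "y": [3.0]})
        with pytest.warns(UserWarning):
            out = standardize_xy(frame)
        assert out.loc[0, "x_std"] == 0.0 and out.loc[0, "y_std"] == 0.0


class TestCountryPooling:
    def test_central_america_pooled(self):
        countries = pd.Series(["AR", "SV", "NI", "PA", "CR", "GT", "BR"])
        pooled = pool_central_america(countries)
        assert pooled.tolist() == ["AR", "CA", "CA", "CA", "CA", "CA", "BR"]


def _sim_glmm(seed, G=15, m=60, beta=(-0.3, 0.4), re_sd=0.5):
    rng = np.random.default_rng(seed)
    n = G * m
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    groups = np.repeat(np.arange(G), m)
    b = rng.normal(0, re_sd, G)
    eta = X @ np.array(beta) + b[groups]
    y = (rng.random(n) < expit(eta)).astype(int)
    return X, y, groups


class TestLogisticGLMM:
    def test_laplace_objective_matches_independent_scalar_laplace(self):
        # dual route: batched objective vs a per-group scalar optimization
        X, y, groups = _sim_glmm(2, G=5, m=40)
        beta, sd = np.array([-0.2, 0.5]), 0.6
        obj = _LaplaceObjective(X, y.astype(float), np.ones((len(y), 1)), groups)
        ours = -obj.neg_loglik(np.concatenate([beta, [np.log(sd)]]))
        total = 0.0
        for g in np.unique(groups):
            idx = groups == g
            off = X[idx] @ beta
            yg = y[idx]

            def neg_g(b):
                eta = off + b
                return -(yg @ eta - np.logaddexp(0, eta).sum() - b * b / (2 * sd * sd))

            res = minimize_scalar(neg_g)
            w = (expit(off + res.x) * (1 - expit(off + res.x))).sum()
            total += -res.fun - 0.5 * np.log(w + 1 / sd**2) - np.log(sd)
        assert ours == pytest.approx(total, abs=1e-6)

    def test_zero_variance_limit_matches_logit_oracle(self):
        X, y, groups = _sim_glmm(3, re_sd=0.0)
        ours = fit_logistic_glmm(X, y, groups, fix_zero_variance=True)
        oracle = sm.Logit(y, X).fit(disp=0)
        assert np.abs(ours.beta - oracle.params).max() < 1e-4
        assert np.abs(ours.se - oracle.bse).max() < 1e-4

    def test_recovers_intercept_re_sd(self):
        X, y, groups = _sim_glmm(4, G=40, m=80, re_sd=0.8)
        res = fit_logistic_glmm(X, y, groups)
        assert res.converged
        assert res.re_sd[0] == pytest.approx(0.8, abs=0.35)
        assert res.beta[1] == pytest.approx(0.4, abs=3 * res.se[1])

    def test_all_ones_separation_error(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(SeparationError):
            fit_logistic_glmm(X, np.ones(50, dtype=int), np.zeros(50))

    def test_rank_deficiency_error(self):
        X = np.ones((3, 4))
        with pytest.raises(RankDeficiencyError):
            fit_logistic_glmm(X, np.array([0, 1, 0]), np.zeros(3))


@pytest.fixture(scope="module")
def analysis_study():
    from streetcover.simulate import SyntheticCityConfig, simulate_study

    return simulate_study(
        8,
        seed=77,
        base_config=SyntheticCityConfig(covariate_noise_sd=2.0),
        size_range_m=(2500.0, 4000.0),
        n_subcities_range=(2, 4),
    )


@pytest.fixture(scope="module")
def analysis_result(analysis_study):
    return run_study_pipeline(analysis_study)


class TestDesigns:
    def test_availability_design_shapes(self, analysis_study, analysis_result):
        design = build_availability_design(
            analysis_result.audited, analysis_study.unit_table, "pct_sewer"
        )
        assert design.X.shape[0] == design.n == len(design.y) == len(design.groups)
        assert design.fe_names[:2] == ["intercept", "pct_sewer"]
        assert "road_length_z" in design.fe_names
        assert design.Z.shape[1] == 3
        # exposure Z-scored over the analysis set
        i = design.fe_names.index("pct_sewer")
        assert design.X[:, i].mean() == pytest.approx(0.0, abs=1e-9)
        assert design.X[:, i].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_index_exposure_enters_untransformed(self, analysis_study, analysis_result):
        design = build_availability_design(
            analysis_result.audited, analysis_study.unit_table, "index_without_poverty"
        )
        i = design.fe_names.index("index_without_poverty")
        assert design.X[:, i].std(ddof=1) != pytest.approx(1.0, abs=1e-3)

    def test_exposure_scaling_equivalence(self, analysis_study, analysis_result):
        units = analysis_study.unit_table
        scaled = units.assign(pop_density=units["pop_density"] * 1000.0)
        d1 = build_availability_design(analysis_result.audited, units, "pop_density")
        d2 = build_availability_design(analysis_result.audited, scaled, "pop_density")
        r1, r2 = fit_availability_model(d1), fit_availability_model(d2)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-6)

    def test_subcity_design_drops_undefined_outcomes(self, analysis_study, analysis_result):
        cov = analysis_result.coverage_subcity
        design = build_subcity_design(
            cov, analysis_study.unit_table, "pct_labor", "sd_age_months"
        )
        assert design.n == cov["sd_age_months"].notna().sum()

    def test_unknown_exposure_rejected(self, analysis_study, analysis_result):
        with pytest.raises(InvalidInputError):
            build_availability_design(
                analysis_result.audited, analysis_study.unit_table, "nope"
            )


class TestSubcityModel:
    def test_noiseless_linear_outcome_recovered_exactly(self, analysis_study, analysis_result):
        units = analysis_study.unit_table
        cov = analysis_result.coverage_subcity.copy()
        meta = units.set_index("subcity_id")
        z = (units["pct_labor"] - units["pct_labor"].mean()) / units["pct_labor"].std(ddof=1)
        exact = 50.0 - 3.0 * z.to_numpy()
        cov["mean_age_months"] = cov["unit_id"].map(
            dict(zip(units["subcity_id"], exact))
        )
        design = build_subcity_design(cov, units, "pct_labor", "mean_age_months")
        res = fit_subcity_model(design)
        # exposure standardization inside the design uses the complete-case
        # set (= all units here), so the coefficient is exactly -3
        assert res.estimate == pytest.approx(-3.0, abs=1e-6)

    def test_zero_re_matches_ols_oracle(self, analysis_study, analysis_result):
        design = build_subcity_design(
            analysis_result.coverage_subcity,
            analysis_study.unit_table,
            "pct_piped_water",
            "mean_age_months",
        )
        ours = fit_subcity_model(design, force_zero_re=True)
        ols = sm.OLS(design.y, design.X).fit()
        i = design.fe_names.index("pct_piped_water")
        assert ours.estimate == pytest.approx(ols.params[i], abs=1e-6)

    def test_rank_deficiency(self, analysis_study, analysis_result):
        cov = analysis_result.coverage_subcity.head(3)
        with pytest.raises((RankDeficiencyError, InvalidInputError)):
            build_subcity_design(
                cov, analysis_study.unit_table, "pct_labor", "mean_age_months"
            )


class TestBattery:
    def test_battery_row_count(self, analysis_study):
        _, battery = run_full_analysis(
            analysis_study,
            exposures=["pop_density", "pct_sewer", "index_without_poverty"],
            outcomes=["availability", "mean_age_months", "sd_age_months"],
        )
        assert len(battery) == 9
        assert set(battery.columns) >= {"outcome", "exposure", "n", "b", "OR", "SE", "p", "converged"}

    def test_full_battery_is_27_rows(self, analysis_study, analysis_result):
        from streetcover.pipeline import ALL_EXPOSURES, ALL_OUTCOMES

        battery = run_model_battery(
            analysis_result.audited,
            analysis_result.coverage_subcity,
            analysis_study.unit_table,
            ALL_EXPOSURES,
            ALL_OUTCOMES,
        )
        assert len(battery) == 27

    def test_per_country_strata_multiply_rows(self, analysis_study, analysis_result):
        battery = run_model_battery(
            analysis_result.audited,
            analysis_result.coverage_subcity,
            analysis_study.unit_table,
            ["pct_sewer"],
            ["mean_age_months"],
            strata="per-country",
        )
        n_countries = pool_central_america(
            analysis_study.unit_table["country"].astype(str)
        ).nunique()
        assert len(battery) == n_countries

    def test_failing_cell_reported_not_raised(self, analysis_study, analysis_result):
        units = analysis_study.unit_table.copy()
        units["pct_piped_water"] = 50.0  # constant -> degenerate z-score
        battery = run_model_battery(
            analysis_result.audited,
            analysis_result.coverage_subcity,
            units,
            ["pct_piped_water", "pct_sewer"],
            ["availability"],
        )
        failed = battery[battery["exposure"] == "pct_piped_water"].iloc[0]
        assert not failed["converged"] and failed["error"]
        assert battery[battery["exposure"] == "pct_sewer"].iloc[0]["converged"]

    def test_row_order_invariance(self, analysis_study, analysis_result):
        audited = analysis_result.audited
        shuffled = audited.sample(frac=1.0, random_state=3).reset_index(drop=True)
        d1 = build_availability_design(audited, analysis_study.unit_table, "pct_labor")
        d2 = build_availability_design(shuffled, analysis_study.unit_table, "pct_labor")
        r1, r2 = fit_availability_model(d1), fit_availability_model(d2)
        # identical up to outer-optimizer tolerance (float summation order
        # differs after a permutation)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-5)
        assert r1.se == pytest.approx(r2.se, rel=1e-3)


class TestModelBasedOutcomes:
    def test_null_effect_estimates_center_near_zero(self, analysis_study, analysis_result):
        rng = np.random.default_rng(10)
        eligible = analysis_result.sample_frame
        eligible = eligible[eligible["eligible"].astype(bool)]
        ests = []
        for _ in range(10):
            audited = draw_point_outcomes(
                eligible, analysis_study.unit_table, rng, beta0=-0.2, beta_ses=0.0
            )
            design = build_availability_design(
                audited, analysis_study.unit_table, "pct_secondary_edu"
            )
            ests.append(fit_availability_model(design).estimate)
        mcse = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) < 4 * mcse + 0.02
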