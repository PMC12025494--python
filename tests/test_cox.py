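import dataclasses

import numpy as np
import pandas as pd
import pytest

import crlandmark as cl
from crlandmark.cox import CoxLandmarkFit, hazard_ratio_at_landmark, wald_tests

from conftest import two_cov_config


def _single_landmark(cohort: pd.DataFrame) -> pd.DataFrame:
    sup = cohort.copy()
    sup.insert(1, "landmark_s", 0.0)
    return sup


@pytest.fixture(scope="module")
def ph_cohort():
    return cl.generate_cohort(two_cov_config(seed=21, censor_rate=0.05), 5000)


@pytest.fixture(scope="module")
def ph_fit(ph_cohort):
    return cl.fit_cause_specific_cox(_single_landmark(ph_cohort), "relapse", ["x1"])


class TestFit:
    def test_recovers_planted_log_hazard_ratio(self, ph_fit):
        se = np.sqrt(ph_fit.cov_robust.loc["x1", "x1"])
        assert abs(ph_fit.params["x1"] - np.log(2)) < 3 * se

    def test_robust_se_near_model_se_with_singleton_clusters(self, ph_fit):
        rob = np.sqrt(ph_fit.cov_robust.loc["x1", "x1"])
        mod = np.sqrt(ph_fit.cov_model.loc["x1", "x1"])
        assert rob == pytest.approx(mod, rel=0.1)

    def test_single_landmark_equals_plain_cause_specific_cox(self, ph_cohort, ph_fit):
        from lifelines import CoxPHFitter

        df = pd.DataFrame(
            {"x1": ph_cohort["x1"], "T": ph_cohort["time"], "E": (ph_cohort["event"] == 1).astype(int)}
        )
        cph = CoxPHFitter().fit(df, "T", "E")
        assert ph_fit.params["x1"] == pytest.approx(cph.params_["x1"], abs=1e-8)

    def test_cause_relabelling_symmetry(self, ph_cohort):
        sup = _single_landmark(ph_cohort)
        swapped = sup.copy()
        swapped["event"] = sup["event"].map({0: 0, 1: 1, 2: 3, 3: 2})
        fit2 = cl.fit_cause_specific_cox(sup, 2, ["x1"], compute_model_cov=False)
        fit3 = cl.fit_cause_specific_cox(swapped, 3, ["x1"], compute_model_cov=False)
        assert fit2.params["x1"] == pytest.approx(fit3.params["x1"], abs=1e-12)

    def test_scaling_continuous_covariate_leaves_fit_invariant(self, small_super):
        # internal standardization makes per-SD coefficients scale-free
        fit_y = cl.fit_cause_specific_cox(small_super, 1, ["age"], compute_model_cov=False)
        months = small_super.copy()
        months["age"] = months["age"] * 12.0
        fit_m = cl.fit_cause_specific_cox(months, 1, ["age"], compute_model_cov=False)
        assert fit_y.params["age"] == pytest.approx(fit_m.params["age"], rel=1e-6)

    def test_errors_on_missing_events_and_constant_terms(self, ph_cohort):
        sup = _single_landmark(ph_cohort)
        none = sup.copy()
        none["event"] = none["event"].replace(2, 0)
        with pytest.raises(ValueError, match="no events"):
            cl.fit_cause_specific_cox(none, 2, ["x1"])
        const = sup.copy()
        const["x1"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cl.fit_cause_specific_cox(const, 1, ["x1"])

    def test_null_covariate_rarely_significant(self):
        hits = 0
        for seed in range(20):
            cohort = cl.generate_cohort(two_cov_config(seed=100 + seed, n_null=1), 1000)
            fit = cl.fit_cause_specific_cox(
                _single_landmark(cohort), 1, ["x1", "z0"], compute_model_cov=False
            )
            se = np.sqrt(fit.cov_robust.loc["z0", "z0"])
            hits += abs(fit.params["z0"]) < 2 * se
        assert hits >= 18  # >=90% of 20 null fits inside 2 robust SEs


def _synthetic_fit(beta, gamma, var_b, var_g, cov_bg=0.0) -> CoxLandmarkFit:
    params = pd.Series({"x": beta, "x:s": gamma})
    cov = pd.DataFrame(
        [[var_b, cov_bg], [cov_bg, var_g]], index=params.index, columns=params.index
    )
    return CoxLandmarkFit(
        cause=1, params=params, cov_robust=cov, cov_model=None,
        term_columns={"x": ["x"]}, scalers={}, interactions=["x"],
        landmark_range=(0.0, 10.0), n_rows=1, n_clusters=1,
    )


class TestHazardRatioReporting:
    def test_no_interaction_means_constant_hr(self, ph_fit):
        hrs = [hazard_ratio_at_landmark(ph_fit, "x1", s)["hr"].iloc[0] for s in (1.0, 3.0, 5.0)]
        assert hrs[0] == hrs[1] == hrs[2] == pytest.approx(np.exp(ph_fit.params["x1"]))

    def test_delta_method_closed_form(self):
        """beta=0.5, gamma=-0.1, robust cov diag(0.01, 0.001):
        HR(3) = exp(0.2), CI = exp(0.2 +- 1.96*sqrt(0.01 + 9*0.001))."""
        fit = _synthetic_fit(0.5, -0.1, 0.01, 0.001)
        row = hazard_ratio_at_landmark(fit, "x", 3.0).iloc[0]
        se = np.sqrt(0.01 + 9 * 0.001)
        assert row["hr"] == pytest.approx(np.exp(0.2), abs=1e-12)
        assert row["ci_low"] == pytest.approx(np.exp(0.2 - 1.959963984540054 * se), abs=1e-10)
        assert row["ci_high"] == pytest.approx(np.exp(0.2 + 1.959963984540054 * se), abs=1e-10)

    def test_delta_method_matches_numerical_variance(self):
        # var(beta + gamma*s) by simulation from the stated normal
        rng = np.random.default_rng(0)
        fit = _synthetic_fit(0.5, -0.1, 0.01, 0.001, cov_bg=0.002)
        draws = rng.multivariate_normal([0.5, -0.1], fit.cov_robust.to_numpy(), size=400_000)
        emp = np.var(draws[:, 0] + 3.0 * draws[:, 1])
        analytic = 0.01 + 9 * 0.001 + 6 * 0.002
        assert emp == pytest.approx(analytic, rel=0.02)
        row = hazard_ratio_at_landmark(fit, "x", 3.0).iloc[0]
        assert np.log(row["ci_high"] / row["hr"]) == pytest.approx(
            1.959963984540054 * np.sqrt(analytic), abs=1e-10
        )

    def test_extrapolation_warns(self, ph_fit):
        with pytest.warns(UserWarning, match="outside fitted range"):
            hazard_ratio_at_landmark(ph_fit, "x1", 5.0)

    def test_report_table_structure(self, small_super):
        fit = cl.fit_cause_specific_cox(
            small_super, 1, ["age", "pM", "combined_resection"], ["pM"], compute_model_cov=False
        )
        table = cl.landmark_hr_table(fit, (1.0, 3.0))
        assert {"hr_1y", "hr_3y", "global_p", "interaction_p"} <= set(table.columns)
        assert set(table["variable"]) == {"age", "pM", "combined_resection", "landmark_decade"}
        pm = table[table["variable"] == "pM"].iloc[0]
        assert np.isfinite(pm["interaction_p"])


class TestWaldTests:
    def test_interaction_p_not_applicable_without_interaction(self, ph_fit):
        out = wald_tests(ph_fit, "x1")
        assert np.isnan(out["interaction_p"])
        assert 0.0 <= out["global_p"] <= 1.0

    def test_strong_effect_is_significant(self, ph_fit):
        assert wald_tests(ph_fit, "x1")["global_p"] < 0.001
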