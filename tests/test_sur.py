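"""SUR/FGLS estimation against OLS oracles and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from trialcea import (
    AnalysisConfig,
    GeneratorConfig,
    adjusted_contrast,
    build_analysis_table,
    fit_sur,
    generate_cohort,
    unadjusted_comparison,
)
from trialcea.sur import EstimationError, SURSpec


def _random_table(seed, n=300, rho=0.5, beta_cost_arm=500.0, beta_eff_arm=0.05):
    """Small synthetic analysis table with known coefficients."""
    rng = np.random.default_rng(seed)
    arm = (rng.random(n) < 0.5).astype(float)
    age = rng.normal(30, 8, n)
    g = rng.integers(0, 3, n)
    base_cost = rng.lognormal(7, 1, n)
    u0 = np.clip(rng.normal(0.85, 0.15, n), -0.661, 1)
    gsi0 = np.clip(rng.normal(30, 10, n), 0, 72)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    eps = rng.multivariate_normal([0, 0], cov, size=n)
    cost = 1000 + beta_cost_arm * arm + 0.3 * base_cost + 5 * age + 400 * eps[:, 0]
    eff = 0.2 + beta_eff_arm * arm + 0.1 * u0 - 0.001 * gsi0 + 0.05 * eps[:, 1]
    return pd.DataFrame(
        {
            "arm_ig": arm,
            "age_years": age,
            "gi_trans_feminine": (g == 1).astype(float),
            "gi_nonbinary": (g == 2).astype(float),
            "baseline_cost": base_cost,
            "eq5d_index_t0": u0,
            "gsi_t0": gsi0,
            "cost_t1": cost,
            "qaly_eq5d": eff,
        }
    )


IDENTICAL = SURSpec(
    cost_covariates=("arm_ig", "age_years", "gi_trans_feminine", "gi_nonbinary"),
    effect_covariates=("arm_ig", "age_years", "gi_trans_feminine", "gi_nonbinary"),
)


class TestFGLS:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_identical_regressors_reduce_to_ols(self, seed):
        """Zellner's result: identical designs make SUR collapse to OLS."""
        table = _random_table(seed, n=150)
        fit = fit_sur(table, IDENTICAL)
        X = sm.add_constant(
            table[["arm_ig", "age_years", "gi_trans_feminine", "gi_nonbinary"]]
        )
        for outcome, params in (
            ("cost_t1", fit.params_cost),
            ("qaly_eq5d", fit.params_effect),
        ):
            ols = sm.OLS(table[outcome], X).fit()
            assert np.allclose(params.to_numpy(), ols.params.to_numpy(), atol=1e-8)

    def test_zero_error_correlation_fgls_approaches_ols(self):
        table = _random_table(11, n=8000, rho=0.0)
        spec = SURSpec()
        fit = fit_sur(table, spec)
        X = sm.add_constant(table[list(spec.cost_covariates)])
        ols = sm.OLS(table["cost_t1"], X).fit()
        # FGLS and OLS converge when the true cross-equation correlation is 0
        assert np.allclose(fit.params_cost.to_numpy(), ols.params.to_numpy(), rtol=5e-2, atol=5e-2)
        assert abs(fit.params_cost["arm_ig"] - ols.params["arm_ig"]) < 20.0

    def test_known_coefficient_recovery(self):
        table = _random_table(5, n=5000, beta_cost_arm=500.0, beta_eff_arm=0.05)
        fit = fit_sur(table, SURSpec())
        se_cost = fit.se("cost", "arm_ig")
        se_eff = fit.se("effect", "arm_ig")
        assert fit.params_cost["arm_ig"] == pytest.approx(500.0, abs=3 * se_cost)
        assert fit.params_effect["arm_ig"] == pytest.approx(0.05, abs=3 * se_eff)

    def test_residual_covariance_psd_and_symmetric(self, analysis_table):
        fit = fit_sur(analysis_table, SURSpec())
        assert np.allclose(fit.sigma, fit.sigma.T)
        assert np.linalg.eigvalsh(fit.sigma).min() >= -1e-10

    def test_rank_deficient_design_names_columns(self):
        table = _random_table(6, n=100)
        table["dup"] = table["age_years"]
        spec = SURSpec(
            cost_covariates=("arm_ig", "age_years", "dup", "baseline_cost"),
            effect_covariates=("arm_ig", "age_years", "eq5d_index_t0", "gsi_t0"),
        )
        with pytest.raises(EstimationError, match="dup|age_years"):
            fit_sur(table, spec)

    def test_too_few_rows(self):
        table = _random_table(7, n=5)
        with pytest.raises(EstimationError):
            fit_sur(table, SURSpec())

    def test_iterated_fgls_converges(self, analysis_table):
        one = fit_sur(analysis_table, SURSpec(), iterate=False)
        it = fit_sur(analysis_table, SURSpec(), iterate=True)
        assert it.iterations >= 1
        # iteration refines but does not move the estimate materially
        assert it.params_cost["arm_ig"] == pytest.approx(
            one.params_cost["arm_ig"], rel=0.05, abs=10.0
        )

    def test_reference_level_swap_leaves_contrast_unchanged(self, analysis_table):
        """Recoding gender indicators (reference level) must not move the
        arm contrast."""
        spec = SURSpec()
        base = fit_sur(analysis_table, spec)
        swapped = analysis_table.copy()
        # swap reference: indicators now for trans_masculine and nonbinary
        swapped["gi_trans_feminine"] = (
            1.0 - swapped["gi_trans_feminine"] - swapped["gi_nonbinary"]
        )
        alt = fit_sur(swapped, spec)
        assert alt.params_cost["arm_ig"] == pytest.approx(
            base.params_cost["arm_ig"], abs=1e-6
        )
        assert alt.params_effect["arm_ig"] == pytest.approx(
            base.params_effect["arm_ig"], abs=1e-9
        )


class TestAdjustedContrast:
    def test_difference_equals_arm_coefficient(self, analysis_table):
        fit = fit_sur(analysis_table, SURSpec())
        c_cost, c_eff = adjusted_contrast(fit, analysis_table)
        assert c_cost.difference == pytest.approx(fit.params_cost["arm_ig"], abs=1e-9)
        assert c_eff.difference == pytest.approx(fit.params_effect["arm_ig"], abs=1e-9)
        assert c_cost.difference == pytest.approx(c_cost.mean_ig - c_cost.mean_cg, abs=1e-9)

    def test_null_simulation_contrast_within_3_se(self):
        table = _random_table(21, n=2000, beta_cost_arm=0.0, beta_eff_arm=0.0)
        fit = fit_sur(table, SURSpec())
        c_cost, c_eff = adjusted_contrast(fit, table)
        assert abs(c_cost.difference) < 3 * c_cost.se
        assert abs(c_eff.difference) < 3 * c_eff.se

    def test_lpm_adjusted_proportions_in_unit_interval(self):
        cohort = generate_cohort(GeneratorConfig(seed=29, n_ig=600, n_cg=600))
        from trialcea import bundled_value_set, default_unit_cost_table

        table = build_analysis_table(
            cohort,
            default_unit_cost_table(),
            bundled_value_set(),
            AnalysisConfig(B=0, effect_measure="RELIABLE_IMPROVEMENT"),
        )
        fit = fit_sur(table, SURSpec(effect_name="RELIABLE_IMPROVEMENT"))
        _, c_eff = adjusted_contrast(fit, table)
        assert 0.0 <= c_eff.mean_ig <= 1.0
        assert 0.0 <= c_eff.mean_cg <= 1.0


class TestUnadjustedComparison:
    def test_identical_samples_give_zero_f(self):
        res = unadjusted_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.difference == 0.0

    def test_complete_separation_with_zero_variance_errors(self):
        with pytest.raises(EstimationError, match="variance"):
            unadjusted_comparison([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_f_equals_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 40), rng.normal(0.3, 1, 35)
        res = unadjusted_comparison(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)
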