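import numpy as np
import pandas as pd
import pytest

from fmisim.imputation import (ImputationModelSpec, draw_posterior,
                               fit_observed_regression, impute_stack,
                               _draw_posterior_batch)
from fmisim.missingness import MaskedCohort, apply_mcar


def _noiseless_masked(n=50, n_missing=10):
    """Y an exact linear function of X: Y = 1 + 2X, no residual noise."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame(0.0, index=range(n),
                        columns=["Y", "X"] + [f"Z{i}" for i in range(1, 12)])
    data["X"] = rng.standard_normal(n)
    data["Y"] = 1.0 + 2.0 * data["X"]
    mask = np.zeros(n, dtype=bool)
    mask[:n_missing] = True
    return MaskedCohort(data=data, mask=mask)


class TestModelSpec:
    def test_analysis_variables_required(self):
        with pytest.raises(ValueError, match="X"):
            ImputationModelSpec(label="bad", predictors=("Z1",), m=10)

    def test_minimum_imputations(self):
        with pytest.raises(ValueError):
            ImputationModelSpec(label="bad", predictors=("X",), m=1)

    def test_canonical_model_lookup(self):
        spec = ImputationModelSpec.canonical("4", m=20)
        assert spec.predictors == ("X", "Z1", "Z2", "Z3", "Z4")
        assert spec.m == 20


class TestFitObservedRegression:
    def test_noiseless_fit_recovers_function(self):
        masked = _noiseless_masked()
        fit = fit_observed_regression(masked,
                                      ImputationModelSpec("m", ("X",), m=5))
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-20)
        assert fit.beta_hat == pytest.approx([1.0, 2.0], abs=1e-10)

    def test_population_slope_on_large_cohort(self, big_cohort):
        # population OLS slope of Y on X alone is Cov(Y,X)/Var(X) = 0.6
        masked = apply_mcar(big_cohort, 0.0)
        fit = fit_observed_regression(masked,
                                      ImputationModelSpec("m", ("X",), m=5))
        se = np.sqrt(0.64 / big_cohort.n)
        assert fit.beta_hat[1] == pytest.approx(0.6, abs=3 * se)

    def test_too_few_complete_rows(self, cohort):
        mask = np.ones(cohort.n, dtype=bool)
        mask[:10] = False  # 10 complete rows, 13-parameter model
        masked = MaskedCohort(data=cohort.data, mask=mask)
        with pytest.raises(ValueError, match="at least"):
            fit_observed_regression(masked, ImputationModelSpec.canonical("5", m=5))

    def test_singular_design_rejected(self, cohort):
        data = cohort.data.copy()
        data["Z1"] = data["X"]  # collinear predictors
        masked = MaskedCohort(data=data, mask=np.zeros(cohort.n, dtype=bool))
        with pytest.raises(ValueError):
            fit_observed_regression(masked, ImputationModelSpec("m", ("X", "Z1"), m=5))


class TestDrawPosterior:
    def test_degenerate_posterior_collapses(self):
        fit = fit_observed_regression(_noiseless_masked(),
                                      ImputationModelSpec("m", ("X",), m=5))
        draw = draw_posterior(fit, np.random.default_rng(1))
        assert draw.sigma_star == 0.0
        assert draw.beta_star == pytest.approx(fit.beta_hat, abs=1e-12)

    def test_posterior_moments(self, cohort):
        """Posterior means match the noninformative-prior closed forms:
        E[beta*] = beta_hat and E[sigma*^2] = s^2 nu / (nu - 2)."""
        masked = apply_mcar(cohort, 0.4)
        fit = fit_observed_regression(masked,
                                      ImputationModelSpec("m", ("X", "Z1"), m=5))
        betas, sigma2 = _draw_posterior_batch(fit, np.random.default_rng(2), 100_000)
        nu = fit.residual_df
        target_s2 = fit.sigma2_hat * nu / (nu - 2)
        assert sigma2.mean() == pytest.approx(
            target_s2, abs=3 * sigma2.std(ddof=1) / np.sqrt(sigma2.size))
        for j in range(betas.shape[1]):
            mcse = betas[:, j].std(ddof=1) / np.sqrt(betas.shape[0])
            assert betas[:, j].mean() == pytest.approx(fit.beta_hat[j], abs=3 * mcse)


class TestImputeStack:
    def test_nothing_to_impute(self, cohort):
        masked = apply_mcar(cohort, 0.0)
        stack = impute_stack(masked, ImputationModelSpec("m", ("X",), m=3), seed=0)
        for j in range(3):
            assert stack.completed(j).equals(cohort.data)

    def test_observed_entries_untouched_and_fills_vary(self, cohort):
        masked = apply_mcar(cohort, 0.4)
        stack = impute_stack(masked, ImputationModelSpec.canonical("3", m=4), seed=1)
        y = stack.completed_y()
        obs = ~masked.mask
        assert np.array_equal(y[:, obs],
                              np.tile(cohort.data.loc[obs, "Y"], (4, 1)))
        # each masked row receives distinct values across imputations
        assert (np.ptp(y[:, masked.mask], axis=0) > 0).all()

    def test_deterministic_under_seed(self, cohort):
        masked = apply_mcar(cohort, 0.2)
        spec = ImputationModelSpec.canonical("2", m=5)
        a = impute_stack(masked, spec, seed=9)
        b = impute_stack(masked, spec, seed=9)
        assert np.array_equal(a.imputed_y, b.imputed_y)

    def test_filled_values_center_on_conditional_mean(self, cohort):
        # law of total expectation: across imputations the mean fill for a
        # masked row equals its OLS prediction, up to MC error of the mean
        mask = np.zeros(cohort.n, dtype=bool)
        mask[17] = True
        masked = MaskedCohort(data=cohort.data, mask=mask)
        spec = ImputationModelSpec("m", ("X", "Z1"), m=2000)
        fit = fit_observed_regression(masked, spec)
        stack = impute_stack(masked, spec, seed=4)
        row = masked.data.iloc[17]
        pred = (fit.beta_hat[0] + fit.beta_hat[1] * row["X"]
                + fit.beta_hat[2] * row["Z1"])
        fills = stack.imputed_y[:, 0]
        tol = 3 * fills.std(ddof=1) / np.sqrt(spec.m)
        assert fills.mean() == pytest.approx(pred, abs=tol)

    def test_between_draw_uncertainty_inflates_variance(self, cohort):
        # parameter uncertainty adds to residual noise, so the spread of the
        # fills across imputations exceeds the residual variance
        masked = apply_mcar(cohort, 0.1)
        spec = ImputationModelSpec("m", ("X",), m=10_000)
        fit = fit_observed_regression(masked, spec)
        stack = impute_stack(masked, spec, seed=8)
        var_fill = stack.imputed_y.var(axis=0, ddof=1)
        assert var_fill.mean() > fit.sigma2_hat

    def test_long_frame_export(self, cohort):
        masked = apply_mcar(cohort, 0.05)
        stack = impute_stack(masked, ImputationModelSpec("m", ("X",), m=3), seed=0)
        long = stack.to_long_frame()
        assert len(long) == 3 * 50
        assert set(long.columns) == {"imputation_index", "row_index", "Y"}
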