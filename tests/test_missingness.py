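import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from fmisim.data_model import CorrelationSpec, simulate_cohort
from fmisim.missingness import (MissingnessScenario, apply_mar, apply_mcar,
                                calibrate_alpha, read_masked_csv,
                                write_masked_csv)
from fmisim.pooling import fit_analysis_model


class TestMcar:
    def test_zero_proportion_is_identity(self, cohort):
        masked = apply_mcar(cohort, 0.0)
        assert masked.n_missing == 0
        assert masked.data.equals(cohort.data)

    def test_exact_count_and_position(self, cohort):
        masked = apply_mcar(cohort, 0.4)
        assert masked.n_missing == 400
        assert masked.mask[:400].all() and not masked.mask[400:].any()

    def test_rejects_total_missingness(self, cohort):
        with pytest.raises(ValueError):
            apply_mcar(cohort, 1.0)

    def test_complete_rows_preserve_joint_distribution(self, cohort):
        # MCAR deletion of iid rows leaves Corr(Y, X) untouched
        masked = apply_mcar(cohort, 0.4)
        d = masked.complete_data
        r = np.corrcoef(d["Y"], d["X"])[0, 1]
        assert abs(r - 0.6) < 3 * (1 - 0.36) / np.sqrt(len(d))


class TestCalibrateAlpha:
    def test_symmetric_case_is_exactly_zero(self):
        assert calibrate_alpha(0.5) == 0.0

    def test_against_monte_carlo_oracle(self):
        """Frozen oracle: bisection on the empirical mean of
        expit(alpha + s), s ~ N(0, sqrt(2)), over 10^7 draws gave
        alpha = -1.8656 for a 20% target (oracle MC SE ~ 1.3e-3)."""
        assert calibrate_alpha(0.2) == pytest.approx(-1.8656, abs=0.01)

    def test_achieved_proportion_matches_target(self):
        # independent check of the quadrature by plain Monte Carlo
        rng = np.random.default_rng(99)
        s = rng.normal(0.0, np.sqrt(2.0), 1_000_000)
        for p in (0.05, 0.4, 0.9):
            alpha = calibrate_alpha(p)
            achieved = expit(alpha + s).mean()
            assert achieved == pytest.approx(p, abs=4 * 0.5 / np.sqrt(s.size) + 1e-4)

    @given(st.tuples(
        st.floats(min_value=0.02, max_value=0.97),
        st.floats(min_value=0.01, max_value=0.5),
    ))
    @settings(max_examples=25, deadline=None)
    def test_strictly_increasing_in_target(self, pq):
        p, dp = pq
        assert calibrate_alpha(p) < calibrate_alpha(min(p + dp, 0.98))


class TestApplyMar:
    def test_requires_calibrated_alpha(self, cohort):
        scen = MissingnessScenario("MAR", 0.4)
        with pytest.raises(ValueError, match="alpha"):
            apply_mar(cohort, scen, seed=0)

    def test_mean_fraction_hits_target(self):
        scen = MissingnessScenario("MAR", 0.4).calibrated()
        spec = CorrelationSpec()
        fracs = []
        for s in range(200):
            cohort = simulate_cohort(spec, seed=1000 + s)
            masked = apply_mar(cohort, scen, seed=2000 + s)
            fracs.append(masked.n_missing / masked.n)
        assert np.mean(fracs) == pytest.approx(0.40, abs=0.01)

    def test_extreme_negative_alpha_masks_nothing(self, cohort):
        scen = MissingnessScenario("MAR", 0.4, alpha=-50.0)
        assert apply_mar(cohort, scen, seed=1).n_missing == 0

    def test_selection_shifts_exposure(self, cohort):
        # positive coefficient on X => rows lost to missingness sit higher on X
        scen = MissingnessScenario("MAR", 0.4).calibrated()
        masked = apply_mar(cohort, scen, seed=7)
        x = cohort.data["X"].to_numpy()
        assert x[masked.mask].mean() > x[~masked.mask].mean()

    def test_deterministic_under_seed(self, cohort):
        scen = MissingnessScenario("MAR", 0.4).calibrated()
        a = apply_mar(cohort, scen, seed=3)
        b = apply_mar(cohort, scen, seed=3)
        assert np.array_equal(a.mask, b.mask)


class TestScenarioValidation:
    def test_mcar_carries_no_alpha(self):
        with pytest.raises(ValueError):
            MissingnessScenario("MCAR", 0.4, alpha=1.0)

    def test_proportion_bounds(self):
        with pytest.raises(ValueError):
            MissingnessScenario("MCAR", 1.0)


def test_masked_csv_round_trip(tmp_path, cohort):
    masked = apply_mcar(cohort, 0.2)
    path = tmp_path / "masked.csv"
    write_masked_csv(masked, path)
    back = read_masked_csv(path)
    assert np.array_equal(back.mask, masked.mask)
    assert np.allclose(back.complete_data.to_numpy(),
                       masked.complete_data.to_numpy())


class TestCompleteCaseBias:
    """Complete-case behaviour of the analysis model under each mechanism."""

    N_REP = 500

    def _cca_slopes(self, mechanism, p, seed0):
        spec = CorrelationSpec()
        scen = (MissingnessScenario("MAR", p).calibrated()
                if mechanism == "MAR" else None)
        slopes = np.empty(self.N_REP)
        for r in range(self.N_REP):
            cohort = simulate_cohort(spec, seed=seed0 + r)
            if mechanism == "MCAR":
                masked = apply_mcar(cohort, p)
            else:
                masked = apply_mar(cohort, scen, seed=seed0 + 10_000 + r)
            slopes[r] = fit_analysis_model(masked, complete_rows_only=True).slope
        return slopes

    def test_unbiased_under_mcar(self):
        slopes = self._cca_slopes("MCAR", 0.4, seed0=50_000)
        mcse = slopes.std(ddof=1) / np.sqrt(self.N_REP)
        assert abs(slopes.mean() - 0.6) < 3 * mcse

    @pytest.mark.parametrize("p", [0.10, 0.40])
    def test_biased_under_mar(self, p):
        slopes = self._cca_slopes("MAR", p, seed0=60_000)
        mcse = slopes.std(ddof=1) / np.sqrt(self.N_REP)
        assert abs(slopes.mean() - 0.6) > 3 * mcse
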