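import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from survtarget import (
    MSMDesign,
    estimate_curves,
    fit_msm,
    fit_msm_from_curves,
    hazards_from_survival,
    msm_variance,
    true_hazards,
    true_msm_coefficients,
    true_survival,
)


def survival_table(dgp):
    return pd.DataFrame(
        [
            {"a": a, "t": t, "estimate": true_survival(a, t, dgp)}
            for a in (0, 1)
            for t in range(1, 5)
        ]
    )


class TestHazardsFromSurvival:
    def test_constant_survival_zero_hazard(self):
        tab = pd.DataFrame({"a": [0, 0, 0], "t": [1, 2, 3], "estimate": [0.9, 0.9, 0.9]})
        out = hazards_from_survival(tab)
        np.testing.assert_allclose(out["hazard"], [0.1, 0.0, 0.0], atol=1e-12)

    def test_first_interval_uses_survival_one(self):
        tab = pd.DataFrame({"a": [1], "t": [1], "estimate": [0.9]})
        assert hazards_from_survival(tab)["hazard"].item() == pytest.approx(0.1)

    def test_matches_closed_form_oracle(self, dgp):
        out = hazards_from_survival(survival_table(dgp))
        truth = true_hazards(dgp)
        merged = out.merge(truth, on=["a", "t"], suffixes=("", "_true"))
        np.testing.assert_allclose(merged["hazard"], merged["hazard_true"], atol=1e-12)
        np.testing.assert_allclose(merged["S_prev"], merged["S_prev_true"], atol=1e-12)

    def test_crossing_estimates_clamped(self, caplog):
        tab = pd.DataFrame({"a": [0, 0], "t": [1, 2], "estimate": [0.9, 0.95]})
        with caplog.at_level("WARNING"):
            out = hazards_from_survival(tab)
        assert out["hazard"].iloc[1] == 0.0

    def test_zero_survival_denominator_rejected(self):
        tab = pd.DataFrame({"a": [0, 0], "t": [1, 2], "estimate": [0.0, 0.0]})
        with pytest.raises(ValueError, match="denominator"):
            hazards_from_survival(tab)


class TestFitMSM:
    def test_oracle_identity_with_true_hazards(self, dgp):
        gamma = fit_msm(true_hazards(dgp), MSMDesign(K=4))
        np.testing.assert_allclose(gamma, true_msm_coefficients(dgp), atol=1e-8)

    def test_saturated_design_interpolates(self, dgp):
        class OneHot:
            def __init__(self, cells):
                self.cells = list(cells)

            def row(self, a, t):
                return np.eye(len(self.cells))[self.cells.index((a, t))]

            def matrix(self, cells):
                return np.vstack([self.row(a, t) for a, t in cells])

        haz = true_hazards(dgp)
        cells = [(int(r.a), int(r.t)) for r in haz.itertuples()]
        gamma = fit_msm(haz, OneHot(cells))
        np.testing.assert_allclose(gamma, logit(haz["hazard"]), atol=1e-8)

    def test_rank_deficiency_rejected(self, dgp):
        with pytest.raises(ValueError, match="rank"):
            fit_msm(true_hazards(dgp), MSMDesign(K=4, formula="a + a + factor(t)"))

    def test_unsupported_term_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            MSMDesign(K=4, formula="a + log(t)")

    def test_linear_time_formula(self, dgp):
        gamma = fit_msm(true_hazards(dgp), MSMDesign(K=4, formula="a + t"))
        assert gamma.size == 3 and gamma[1] == pytest.approx(-1.0, abs=0.01)


class TestMSMVariance:
    def test_zero_ic_zero_covariance(self, dgp):
        design = MSMDesign(K=4)
        gamma = fit_msm(true_hazards(dgp), design)
        ic = {(a, t): np.zeros(100) for a in (0, 1) for t in range(1, 5)}
        cov = msm_variance(gamma, design, survival_table(dgp), ic)
        np.testing.assert_allclose(cov, 0.0, atol=1e-14)

    def test_single_cell_delta_method(self):
        # K = 1, one exposure level: gamma = logit(1 - S), so
        # Var(gamma) = Var(S) / [S(1-S)]^2 by the univariate delta method
        class Cell:
            def row(self, a, t):
                return np.array([1.0])

            def matrix(self, cells):
                return np.ones((len(cells), 1))

        rng = np.random.default_rng(0)
        ic = rng.normal(0, 0.5, size=5000)
        ic -= ic.mean()
        s_hat = 0.8
        surv = pd.DataFrame({"a": [1], "t": [1], "estimate": [s_hat]})
        gamma = np.array([logit(1 - s_hat)])
        cov = msm_variance(gamma, Cell(), surv, {(1, 1): ic})
        var_s = ic.var(ddof=1) / ic.size
        expected = var_s / (s_hat * (1 - s_hat)) ** 2
        assert cov[0, 0] == pytest.approx(expected, abs=1e-8 * expected)

    def test_covariance_symmetric_psd(self, curves5000):
        res = fit_msm_from_curves(curves5000)
        np.testing.assert_allclose(res.covariance, res.covariance.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(res.covariance) > -1e-12)
        summ = res.summary()
        assert np.all(summ["ci_low"] <= summ["estimate"])
        assert np.all(summ["estimate"] <= summ["ci_high"])

    def test_estimated_msm_near_truth(self, curves5000, dgp):
        res = fit_msm_from_curves(curves5000)
        truth = true_msm_coefficients(dgp)
        z = (res.gamma[1] - truth[1]) / res.se[1]
        assert abs(z) < 4
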