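import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from survtarget import (
    DGPParams,
    LogisticLearner,
    NuisanceFits,
    WideSurvivalData,
    clever_weights,
    estimate_ate,
    estimate_curves,
    estimate_survival,
    generate,
    target_step,
    true_survival,
)


class TestCleverWeights:
    def test_zero_off_regime_and_after_censoring(self, cohort5000):
        data = cohort5000.data
        fits = NuisanceFits.fit(data)
        for a in (0, 1):
            w, _ = clever_weights(a, 2, fits, data)
            assert np.all(w[data.exposure != a] == 0)
            assert np.all(w[data.censor[:, 1] == 1] == 0)
            assert np.all(w[(data.exposure == a) & (data.censor[:, 1] == 0)] > 0)

    def test_closed_form_with_constant_propensity(self):
        # no censoring and P(A=1|L) = 1/2 gives weight 2 for regime-followers
        n = 400
        rng = np.random.default_rng(0)
        data = WideSurvivalData(
            baseline=pd.DataFrame({"L": np.zeros(n)}),
            exposure=rng.integers(0, 2, n),
            censor=np.zeros((n, 2)),
            event=np.column_stack([rng.integers(0, 2, n)] * 2).astype(float),
        )
        fits = NuisanceFits.fit(data, exposure_learner=LogisticLearner())
        w, n_trunc = clever_weights(1, 1, fits, data)
        follows = data.exposure == 1
        np.testing.assert_allclose(w[follows], 1.0 / follows.mean(), rtol=1e-6)
        assert n_trunc == 0

    def test_mean_one_under_correct_models(self, cohort5000):
        data = cohort5000.data
        fits = NuisanceFits.fit(data)
        for a in (0, 1):
            w, _ = clever_weights(a, 1, fits, data)
            assert abs(w.mean() - 1.0) < 0.05

    def test_invalid_gbound(self, cohort2000):
        fits = NuisanceFits.fit(cohort2000.data)
        with pytest.raises(ValueError, match="gbound"):
            clever_weights(1, 1, fits, cohort2000.data, gbound=0.7)


class TestTargetStep:
    def test_zero_weights_no_update(self):
        q = np.full(10, 0.4)
        eps, q_star = target_step(q, np.ones(10), np.zeros(10), np.ones(10, dtype=bool))
        assert eps == 0.0
        np.testing.assert_allclose(q_star, 0.4, atol=1e-9)

    def test_fixed_point(self):
        # initial predictions already solving the score equation stay put
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 1000).astype(float)
        q = np.full(1000, y.mean())
        eps, _ = target_step(q, y, np.ones(1000), np.ones(1000, dtype=bool))
        assert abs(eps) < 1e-8

    def test_closed_form_intercept_update(self):
        # offset logit(0.5) = 0, so eps equals the logit of the weighted mean
        rng = np.random.default_rng(2)
        y = (rng.uniform(size=2000) < 0.8).astype(float)
        w = rng.uniform(0.5, 2.0, size=2000)
        q = np.full(2000, 0.5)
        eps, q_star = target_step(q, y, w, np.ones(2000, dtype=bool))
        target = np.average(y, weights=w)
        assert eps == pytest.approx(logit(target), abs=1e-9)
        np.testing.assert_allclose(q_star, target, atol=1e-9)


class TestEstimateSurvival:
    def test_score_equations_and_centered_ic(self, curves2000):
        for res in curves2000.results.values():
            for j, resid in res.score_residuals.items():
                assert abs(resid) < 1e-6, (res.a, res.t, j)
            assert abs(res.influence_curve.mean()) < 1e-6

    def test_estimates_near_truth_at_n5000(self, curves5000, dgp):
        for (a, t), res in curves5000.results.items():
            truth = true_survival(a, t, dgp)
            assert abs(res.estimate - truth) < 4 * res.se
            assert res.ci_low <= res.estimate <= res.ci_high
            assert 0 <= res.estimate <= 1

    def test_oracle_equivalence_saturated_no_censoring(self, no_censoring_cohort):
        # with binary L, saturated models and no censoring, targeting is a
        # fixed point and TMLE equals the nonparametric standardized estimate
        data = no_censoring_cohort.data
        L = data.baseline["L"].to_numpy()
        for a in (0, 1):
            res = estimate_survival(
                data, a, 1,
                outcome_learner=LogisticLearner(interactions=True),
            )
            plug_in = sum(
                np.mean(L == ell) * (1 - data.event[(data.exposure == a) & (L == ell), 0].mean())
                for ell in (0.0, 1.0)
            )
            assert res.estimate == pytest.approx(plug_in, abs=1e-10)
            assert max(abs(e) for e in res.epsilons.values()) < 1e-8

    def test_null_effect_gives_equal_arms(self):
        params = DGPParams(beta_a=0.0, alpha=(-1.0, 0.0))
        data = generate(params, n=20_000, seed=4).data
        curves = estimate_curves(data, times=(2,))
        r1, r0 = curves[(1, 2)], curves[(0, 2)]
        assert abs(r1.estimate - r0.estimate) < 4 * np.hypot(r1.se, r0.se)

    def test_t_out_of_range(self, cohort2000):
        with pytest.raises(ValueError):
            estimate_survival(cohort2000.data, 1, 5)


class TestATE:
    def test_identical_inputs_zero_effect_zero_se(self, curves5000):
        r = curves5000[(1, 2)]
        out = estimate_ate(r, r)
        assert out.estimate == 0.0 and out.se == 0.0

    def test_mismatched_targets_rejected(self, curves5000):
        with pytest.raises(ValueError):
            estimate_ate(curves5000[(1, 1)], curves5000[(0, 2)])

    def test_ate_near_truth(self, curves5000, dgp):
        out = curves5000.ate(4)
        truth = true_survival(1, 4, dgp) - true_survival(0, 4, dgp)
        assert abs(out.estimate - truth) < 4 * out.se
        assert out.ci_low <= out.estimate <= out.ci_high
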