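"""Targeted maximum likelihood estimation of counterfactual survival.

For a point exposure level a and horizon t, the estimator runs a backward
recursion over intervals j = t, ..., 1. At each step an event /
iterated-expectation model is fitted on the risk set {C_j = 0, Y_{j-1} = 0},
its counterfactual predictions (exposure set to a) are *targeted* by a
weighted intercept-only logistic fluctuation with the logit of the initial
predictions as offset, and the updated predictions become the response of
the next step. The fluctuation weights are the inverse-probability
"clever weights"

    H_a(j) = I(A = a, C_j = 0) / [ g_A(a | L1) * prod_{k<=j} P(C_k = 0 | ...) ],

with every probability in the denominator floored at ``gbound``. Because the
fluctuation solves the weighted score equation exactly, the final estimator
solves the efficient-influence-curve estimating equation, which yields both
double robustness and a simple variance estimator: the sample variance of
the accumulated influence curve divided by n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data_model import WideSurvivalData
from .learners import LogisticLearner
from .nuisance import NuisanceFits, covariate_frame, fit_outcome_step

logger = logging.getLogger(__name__)

__all__ = [
    "TMLEResult",
    "ATEResult",
    "SurvivalCurves",
    "clever_weights",
    "target_step",
    "estimate_survival",
    "estimate_ate",
    "estimate_curves",
]

_Z95 = 1.959963984540054
_Q_CLAMP = 1e-6


@dataclass
class TMLEResult:
    """Targeted estimate of S_a(t) with influence-curve inference."""

    a: int
    t: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    influence_curve: np.ndarray
    epsilons: dict[int, float]
    score_residuals: dict[int, float]  # weighted residual sum after each update
    updated_q1: np.ndarray  # Q*_a(1, .) per subject, used for the MSM variance
    truncation_count: int

    @property
    def n(self) -> int:
        return self.influence_curve.size


@dataclass
class ATEResult:
    t: int
    levels: tuple[int, int]
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    influence_curve: np.ndarray


def clever_weights(
    a: int,
    j: int,
    nuisance: NuisanceFits,
    data: WideSurvivalData,
    gbound: float = 0.005,
) -> tuple[np.ndarray, int]:
    """Inverse-probability weights H_a(j) and the number of floored probabilities.

    Zero for subjects not following regime a or censored by interval j;
    otherwise the inverse of the (gbound-floored) exposure probability times
    the cumulative probability of remaining uncensored through j.
    """
    if not 0.0 < gbound < 0.5:
        raise ValueError("gbound must lie in (0, 0.5)")
    follows = (np.asarray(data.exposure) == a) & data.uncensored_through(j)
    g = nuisance.exposure_prob(a)
    n_trunc = int(np.sum((g < gbound) & follows))
    g = np.maximum(g, gbound)
    denom = g.copy()
    for k in range(1, j + 1):
        pk = 1.0 - nuisance.censor_prob(k, a)
        n_trunc += int(np.sum((pk < gbound) & follows))
        denom = denom * np.maximum(pk, gbound)
    return np.where(follows, 1.0 / denom, 0.0), n_trunc


def target_step(
    initial_predictions: np.ndarray,
    response: np.ndarray,
    weights: np.ndarray,
    riskset: np.ndarray,
) -> tuple[float, np.ndarray]:
    """One fluctuation: intercept-only weighted logistic update on an offset.

    Solves sum_{riskset} H_i (response_i - expit(logit(Q_i) + eps)) = 0 for
    the scalar eps and returns the updated predictions
    Q* = expit(logit(Q) + eps) for *all* subjects (entries with missing Q
    stay missing). With zero total weight on the risk set there is no
    information to update and eps = 0.
    """
    Q = np.clip(np.asarray(initial_predictions, dtype=float), _Q_CLAMP, 1.0 - _Q_CLAMP)
    offset = logit(Q)
    w = np.asarray(weights, dtype=float)[riskset]
    y = np.asarray(response, dtype=float)[riskset]
    off = offset[riskset]
    use = w > 0
    if not use.any() or np.nansum(w) == 0:
        logger.warning("targeting step: zero total weight on the risk set; eps = 0")
        return 0.0, expit(offset)
    w, y, off = w[use], y[use], off[use]

    def score(eps: float) -> float:
        return float(np.sum(w * (y - expit(off + eps))))

    # the score is strictly decreasing in eps: bracket a sign change
    lo, hi = -1.0, 1.0
    while score(lo) <= 0 and lo > -40:
        lo *= 2
    while score(hi) >= 0 and hi < 40:
        hi *= 2
    s_lo, s_hi = score(lo), score(hi)
    if s_lo * s_hi > 0:
        # no sign change within a huge bracket: responses sit at a boundary
        eps = lo if abs(s_lo) < abs(s_hi) else hi
    else:
        eps = brentq(score, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return float(eps), expit(offset + eps)


def estimate_survival(
    data: WideSurvivalData,
    a: int,
    t: int,
    nuisance: NuisanceFits | None = None,
    outcome_learner=None,
    lookback: int | None = None,
    gbound: float = 0.005,
) -> TMLEResult:
    """Targeted estimate of the counterfactual survival S_a(t).

    Runs the backward recursion described in the module docstring and
    returns the point estimate 1 - mean(Q*_a(1, .)), the per-subject
    influence curve, and a 95% Wald interval.
    """
    if not 1 <= t <= data.K:
        raise ValueError(f"t must lie in 1..K={data.K}")
    outcome_learner = outcome_learner or LogisticLearner()
    if nuisance is None:
        nuisance = NuisanceFits.fit(data, lookback=lookback, through=t)

    n = data.n
    ic = np.zeros(n)
    epsilons: dict[int, float] = {}
    score_residuals: dict[int, float] = {}
    n_trunc_total = 0
    response = data.event[:, t - 1].copy()  # observed Y_t; missing if censored
    q_star = np.full(n, np.nan)
    for j in range(t, 0, -1):
        riskset = data.uncensored_through(j) & ~data.event_before(j)
        model = fit_outcome_step(data, j, response, lookback, outcome_learner)
        alive_prev = data.uncensored_through(j - 1)
        X_a = covariate_frame(data, j, lookback, exposure_level=a)
        q = np.full(n, np.nan)
        q[alive_prev] = model.predict(X_a.loc[alive_prev])
        q[data.event_before(j)] = 1.0  # Y_{j-1} = 1 forces Y_j = 1
        weights, n_trunc = clever_weights(a, j, nuisance, data, gbound)
        n_trunc_total += n_trunc
        eps, q_star = target_step(q, response, weights, riskset)
        q_star[data.event_before(j)] = 1.0
        epsilons[j] = eps
        contrib = np.where(weights > 0, np.nan_to_num(weights * (q_star - response)), 0.0)
        score_residuals[j] = float(-np.sum(contrib))
        ic += contrib
        response = q_star
    mean_q1 = float(np.mean(q_star))
    estimate = 1.0 - mean_q1
    ic += mean_q1 - q_star
    se = float(np.sqrt(np.var(ic, ddof=1) / n)) if n > 1 else float("nan")
    return TMLEResult(
        a=a,
        t=t,
        estimate=estimate,
        se=se,
        ci_low=estimate - _Z95 * se,
        ci_high=estimate + _Z95 * se,
        influence_curve=ic,
        epsilons=epsilons,
        score_residuals=score_residuals,
        updated_q1=q_star,
        truncation_count=n_trunc_total,
    )


def estimate_ate(result_1: TMLEResult, result_0: TMLEResult) -> ATEResult:
    """Treatment-effect contrast S_{a1}(t) - S_{a0}(t) with Wald inference.

    The influence curve of the contrast is the difference of the two
    survival influence curves, so the variance accounts for their
    correlation within subjects.
    """
    if result_1.t != result_0.t or result_1.n != result_0.n:
        raise ValueError("ATE requires results for the same horizon and data")
    est = result_1.estimate - result_0.estimate
    ic = result_1.influence_curve - result_0.influence_curve
    n = ic.size
    se = float(np.sqrt(np.var(ic, ddof=1) / n)) if n > 1 else float("nan")
    return ATEResult(
        t=result_1.t,
        levels=(result_1.a, result_0.a),
        estimate=est,
        se=se,
        ci_low=est - _Z95 * se,
        ci_high=est + _Z95 * se,
        influence_curve=ic,
    )


@dataclass
class SurvivalCurves:
    """Targeted survival estimates for a grid of exposure levels and horizons."""

    results: dict[tuple[int, int], TMLEResult]
    levels: tuple[int, ...]
    times: tuple[int, ...]

    def __getitem__(self, key: tuple[int, int]) -> TMLEResult:
        return self.results[key]

    def survival(self, a: int, t: int) -> float:
        if t == 0:
            return 1.0
        return self.results[(a, t)].estimate

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "a": r.a,
                "t": r.t,
                "estimate": r.estimate,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_truncated": r.truncation_count,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows).sort_values(["a", "t"]).reset_index(drop=True)

    def ate(self, t: int, a1: int | None = None, a0: int | None = None) -> ATEResult:
        a1 = max(self.levels) if a1 is None else a1
        a0 = min(self.levels) if a0 is None else a0
        return estimate_ate(self.results[(a1, t)], self.results[(a0, t)])

    def ic_matrix(self) -> dict[tuple[int, int], np.ndarray]:
        return {key: r.influence_curve for key, r in self.results.items()}


def estimate_curves(
    data: WideSurvivalData,
    levels: tuple[int, ...] | None = None,
    times: tuple[int, ...] | None = None,
    exposure_learner=None,
    censoring_learner=None,
    outcome_learner=None,
    lookback: int | None = None,
    gbound: float = 0.005,
) -> SurvivalCurves:
    """Run the targeted estimator for every (level, horizon) pair.

    The exposure and censoring fits are shared across targets; the outcome
    recursion is run independently for each horizon because the iterated
    responses at j < t depend on t.
    """
    levels = tuple(int(v) for v in data.exposure_levels) if levels is None else tuple(levels)
    times = tuple(range(1, data.K + 1)) if times is None else tuple(times)
    nuisance = NuisanceFits.fit(
        data,
        exposure_learner=exposure_learner,
        censoring_learner=censoring_learner,
        lookback=lookback,
        through=max(times),
    )
    results = {
        (a, t): estimate_survival(
            data, a, t, nuisance=nuisance, outcome_learner=outcome_learner,
            lookback=lookback, gbound=gbound,
        )
        for a in levels
        for t in times
    }
    return SurvivalCurves(results=results, levels=levels, times=times)
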