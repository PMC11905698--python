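"""Synthetic discrete-time survival data with known counterfactual truth.

The generator produces a point binary exposure A confounded by a single
binary baseline covariate L, per-interval event hazards that are logistic in
L with an additive exposure effect on the log-odds scale, and light
missing-at-random censoring depending on A and L:

    L ~ Bernoulli(p_L)
    P(A = 1 | L)                        = expit(alpha0 + alpha1 L)
    P(Y_t^a = 1 | Y_{t-1}^a = 0, L)     = expit(beta0 + beta_a a + beta_L L)
    P(C_t = 1 | C_{t-1} = 0, A, L, Y_{t-1} = 0) = expit(delta0 + delta_A A + delta_L L)

Both the event and censoring processes are absorbing, and event indicators
become missing once a subject is censored. Because L is binary, every
counterfactual estimand has a closed form as a two-point mixture over L,
which this module exposes alongside the sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import WideSurvivalData
from .learners import fit_weighted_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "DGPParams",
    "GeneratedData",
    "generate",
    "true_survival",
    "true_hazards",
    "true_msm_coefficients",
    "default_msm_design_row",
]


@dataclass(frozen=True)
class DGPParams:
    """Coefficients of the data-generating process (defaults as described above)."""

    p_L: float = 0.5
    alpha: tuple[float, float] = (-3.0, 0.6)  # exposure: intercept, L slope
    beta0: float = -2.0  # event hazard intercept
    beta_a: float = -1.0  # additive exposure effect on the hazard log-odds
    beta_L: float = 0.25  # event hazard L slope
    delta: tuple[float, float, float] = (-5.0, 0.2, 0.2)  # censoring: int., A, L
    K: int = 4

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be at least 1")
        if not 0.0 <= self.p_L <= 1.0:
            raise ValueError("p_L must be a probability")

    def event_hazard(self, a: int, L: np.ndarray | float) -> np.ndarray:
        return expit(self.beta0 + self.beta_a * a + self.beta_L * np.asarray(L, dtype=float))

    def censor_hazard(self, A: np.ndarray, L: np.ndarray) -> np.ndarray:
        d0, dA, dL = self.delta
        return expit(d0 + dA * np.asarray(A, dtype=float) + dL * np.asarray(L, dtype=float))


@dataclass
class GeneratedData:
    """Observed data plus, optionally, the full counterfactual event matrices."""

    data: WideSurvivalData
    counterfactual_events: dict[int, np.ndarray] | None = None


def generate(
    params: DGPParams,
    n: int,
    seed: int | np.random.Generator = 0,
    include_counterfactuals: bool = False,
) -> GeneratedData:
    """Draw ``n`` subjects from the data-generating process.

    Random draws are consumed in the fixed order L, A, then per interval the
    censoring uniform followed by the event uniform, so a given seed is
    reproducible within this implementation. The same event uniform drives
    both counterfactual arms (a rank-preserving coupling), which makes the
    consistency property Y_t = Y_t^A hold row by row exactly.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = params.K
    L = (rng.uniform(size=n) < params.p_L).astype(float)
    a0, a1 = params.alpha
    A = (rng.uniform(size=n) < expit(a0 + a1 * L)).astype(int)

    cf = {0: np.zeros((n, K)), 1: np.zeros((n, K))}
    censor = np.zeros((n, K))
    event = np.full((n, K), np.nan)
    censored = np.zeros(n, dtype=bool)
    observed_prev = np.zeros(n)  # Y_{t-1} under the observed exposure
    for t in range(1, K + 1):
        u_c = rng.uniform(size=n)
        u_y = rng.uniform(size=n)
        # censoring first (C_t precedes Y_t); hazard applies while event-free
        newly_censored = (~censored) & (observed_prev == 0) & (
            u_c < params.censor_hazard(A, L)
        )
        censored = censored | newly_censored
        censor[:, t - 1] = censored.astype(float)
        for a in (0, 1):
            prev = cf[a][:, t - 2] if t > 1 else np.zeros(n)
            cf[a][:, t - 1] = np.where(
                prev == 1, 1.0, (u_y < params.event_hazard(a, L)).astype(float)
            )
        observed_cf = np.where(A == 1, cf[1][:, t - 1], cf[0][:, t - 1])
        event[:, t - 1] = np.where(censored, np.nan, observed_cf)
        observed_prev = np.where(censored, observed_prev, observed_cf)

    data = WideSurvivalData(
        baseline=pd.DataFrame({"L": L}),
        exposure=A,
        censor=censor,
        event=event,
    )
    return GeneratedData(
        data=data,
        counterfactual_events=cf if include_counterfactuals else None,
    )


def true_survival(a: int, t: int, params: DGPParams = DGPParams()) -> float:
    """Closed-form counterfactual survival S_a(t) = E_L[(1 - h_a(L))^t].

    With a binary covariate the expectation over L is a two-point mixture, so
    the value is exact. ``t = 0`` returns 1 by convention.
    """
    if t < 0 or t > params.K:
        raise ValueError(f"t must lie in 0..K={params.K}")
    if t == 0:
        return 1.0
    pl = params.p_L
    s = 0.0
    for ell, w in ((0.0, 1.0 - pl), (1.0, pl)):
        s += w * (1.0 - params.event_hazard(a, ell)) ** t
    return float(s)


def true_hazards(params: DGPParams = DGPParams(), levels: tuple[int, ...] = (0, 1)) -> pd.DataFrame:
    """Marginal discrete hazards lambda_a(t) = (S_a(t-1) - S_a(t)) / S_a(t-1)."""
    rows = []
    for a in levels:
        for t in range(1, params.K + 1):
            s_prev = true_survival(a, t - 1, params)
            s_t = true_survival(a, t, params)
            rows.append({"a": a, "t": t, "hazard": (s_prev - s_t) / s_prev, "S_prev": s_prev})
    return pd.DataFrame(rows)


def default_msm_design_row(a: int, t: int, K: int) -> np.ndarray:
    """Design row (1, a, I(t=2), ..., I(t=K)) of the default working model."""
    return np.array([1.0, float(a)] + [1.0 if t == k else 0.0 for k in range(2, K + 1)])


def true_msm_coefficients(
    params: DGPParams = DGPParams(),
    design_row=None,
    levels: tuple[int, ...] = (0, 1),
) -> np.ndarray:
    """Working-model coefficients implied by the exact counterfactual hazards.

    Fits a weighted logistic regression of the true hazards lambda_a(t) on the
    design rows X_{a,t}, one pseudo-observation per (a, t) cell, weighted by
    S_a(t-1). Hazards are probabilities (fractions), so the fit is a
    quasi-binomial mean fit rather than a likelihood on 0/1 outcomes.
    """
    if design_row is None:
        design_row = lambda a, t: default_msm_design_row(a, t, params.K)  # noqa: E731
    haz = true_hazards(params, levels)
    X = np.vstack([design_row(int(r.a), int(r.t)) for r in haz.itertuples()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("MSM design matrix is rank deficient")
    res = fit_weighted_logistic(
        X, haz["hazard"].to_numpy(), weights=haz["S_prev"].to_numpy(), tol=1e-12
    )
    return res.params
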