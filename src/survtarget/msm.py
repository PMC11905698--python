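"""Marginal structural model for the counterfactual discrete-time hazard.

Once counterfactual survival probabilities S_a(t) have been estimated for
every exposure level a and interval t, the implied hazards

    lambda_a(t) = (S_a(t-1) - S_a(t)) / S_a(t-1),    S_a(0) = 1,

are summarised by a working model logit[lambda_a(t)] = X_{a,t}' gamma fitted
by weighted logistic regression on the m*K pseudo-observations, one per
(a, t) cell, with weights S_a(t-1). Because gamma is a smooth function of
the survival table, its sampling variance follows from the survival
influence curves by the functional delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .learners import fit_weighted_logistic
from .tmle import SurvivalCurves

logger = logging.getLogger(__name__)

__all__ = ["MSMDesign", "MSMResult", "hazards_from_survival", "fit_msm", "msm_variance", "fit_msm_from_curves"]

_Z95 = 1.959963984540054
_HAZ_CLAMP = 1e-10


@dataclass(frozen=True)
class MSMDesign:
    """Builds the design row X_{a,t} from a formula in ``a`` and ``t``.

    The formula is a '+'-separated list of terms among: ``a`` (exposure
    level, linear), ``t`` (interval, linear), ``a:t`` (product), and
    ``factor(t)`` (indicator columns for t = 2..K). An intercept is always
    included. The default, ``"a + factor(t)"``, matches a constant exposure
    effect with unrestricted time main effects.
    """

    K: int
    formula: str = "a + factor(t)"

    def __post_init__(self) -> None:
        for term in self.terms:
            if term not in {"1", "a", "t", "a:t", "factor(t)"}:
                raise ValueError(f"unsupported MSM term: {term!r}")

    @property
    def terms(self) -> list[str]:
        return [s.strip() for s in self.formula.split("+") if s.strip()]

    @property
    def column_names(self) -> list[str]:
        names = ["(Intercept)"]
        for term in self.terms:
            if term == "1":
                continue
            if term == "factor(t)":
                names += [f"t={k}" for k in range(2, self.K + 1)]
            else:
                names.append(term)
        return names

    def row(self, a: int, t: int) -> np.ndarray:
        vals = [1.0]
        for term in self.terms:
            if term == "1":
                continue
            if term == "a":
                vals.append(float(a))
            elif term == "t":
                vals.append(float(t))
            elif term == "a:t":
                vals.append(float(a) * float(t))
            elif term == "factor(t)":
                vals += [1.0 if t == k else 0.0 for k in range(2, self.K + 1)]
        return np.array(vals)

    def matrix(self, cells: list[tuple[int, int]]) -> np.ndarray:
        X = np.vstack([self.row(a, t) for a, t in cells])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("MSM design matrix is rank deficient")
        return X


def hazards_from_survival(survival: pd.DataFrame) -> pd.DataFrame:
    """Hazard table from a survival table with columns (a, t, estimate).

    S_a(0) is taken as 1. Raw hazards outside [0, 1] (possible when
    finite-sample survival estimates cross) are clamped with a warning.
    """
    out = []
    for a, grp in survival.groupby("a"):
        grp = grp.sort_values("t")
        s_prev = 1.0
        for r in grp.itertuples():
            if s_prev <= 0:
                raise ValueError(f"zero survival in a hazard denominator at (a={a}, t={r.t})")
            lam = (s_prev - r.estimate) / s_prev
            if lam < 0 or lam > 1:
                logger.warning("hazard clamped to [0,1] at (a=%s, t=%s): %.4f", a, r.t, lam)
                lam = float(np.clip(lam, 0.0, 1.0))
            out.append({"a": a, "t": int(r.t), "hazard": lam, "S_prev": s_prev})
            s_prev = r.estimate
    return pd.DataFrame(out)


def fit_msm(hazards: pd.DataFrame, design: MSMDesign) -> np.ndarray:
    """Weighted quasi-binomial fit of the working model on the hazard table.

    One pseudo-observation per (a, t) cell with outcome lambda_a(t) and
    weight S_a(t-1); hazards at exactly 0 or 1 are nudged inside the open
    interval to keep the logit finite.
    """
    cells = [(int(r.a), int(r.t)) for r in hazards.itertuples()]
    X = design.matrix(cells)
    lam = np.clip(hazards["hazard"].to_numpy(), _HAZ_CLAMP, 1.0 - _HAZ_CLAMP)
    w = hazards["S_prev"].to_numpy()
    if np.any(w <= 0):
        raise ValueError("non-positive pseudo-observation weight")
    res = fit_weighted_logistic(X, lam, weights=w, tol=1e-12)
    return np.asarray(res.params)


def msm_variance(
    gamma: np.ndarray,
    design: MSMDesign,
    survival: pd.DataFrame,
    ic_matrix: dict[tuple[int, int], np.ndarray],
) -> np.ndarray:
    """Delta-method covariance of gamma from the survival influence curves.

    Writing p_{a,t} = expit(X_{a,t}' gamma), the estimating function of the
    weighted fit is U(gamma, S) = sum_{a,t} [S_a(t-1) - S_a(t)
    - S_a(t-1) p_{a,t}] X_{a,t}, so the per-subject influence curve of gamma
    is B^{-1} sum_{a,t} [-X_{a,t} + X_{a,t+1} (1 - p_{a,t+1})] IC_a(t)
    with bread B = sum_{a,t} S_a(t-1) p_{a,t} (1 - p_{a,t}) X X'. At t = K
    there is no t+1 design row and that term vanishes. The covariance is the
    sample variance of the per-subject rows divided by n.
    """
    gamma = np.asarray(gamma, dtype=float)
    surv = {(int(r.a), int(r.t)): r.estimate for r in survival.itertuples()}
    levels = sorted({a for a, _ in surv})
    times = sorted({t for _, t in surv})
    K = max(times)

    def s_prev(a, t):
        return 1.0 if t == 1 else surv[(a, t - 1)]

    p = {(a, t): float(expit(design.row(a, t) @ gamma)) for a in levels for t in times}
    dim = design.row(levels[0], 1).size
    bread = np.zeros((dim, dim))
    for a in levels:
        for t in times:
            x = design.row(a, t)
            bread += s_prev(a, t) * p[(a, t)] * (1 - p[(a, t)]) * np.outer(x, x)
    n = next(iter(ic_matrix.values())).size
    meat_rows = np.zeros((n, dim))
    for a in levels:
        for t in times:
            coef = -design.row(a, t)
            if t < K:
                coef = coef + design.row(a, t + 1) * (1 - p[(a, t + 1)])
            meat_rows += np.outer(ic_matrix[(a, t)], coef)
    bread_inv = np.linalg.inv(bread)
    ic_gamma = meat_rows @ bread_inv.T
    centered = ic_gamma - ic_gamma.mean(axis=0)
    return centered.T @ centered / (n - 1) / n


@dataclass
class MSMResult:
    """Fitted working-model coefficients with influence-curve covariance."""

    design: MSMDesign
    gamma: np.ndarray
    covariance: np.ndarray
    hazards: pd.DataFrame

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def summary(self) -> pd.DataFrame:
        """Coefficient table; exp(estimate) is an odds ratio in general and
        approximates a hazard ratio only where the fitted hazards are small
        (below about 0.1)."""
        se = self.se
        return pd.DataFrame(
            {
                "coefficient": self.design.column_names,
                "estimate": self.gamma,
                "se": se,
                "ci_low": self.gamma - _Z95 * se,
                "ci_high": self.gamma + _Z95 * se,
                "exp(estimate)": np.exp(self.gamma),
            }
        )


def fit_msm_from_curves(curves: SurvivalCurves, formula: str = "a + factor(t)") -> MSMResult:
    """Fit the hazard MSM to targeted survival estimates, with delta-method SEs."""
    table = curves.table()
    design = MSMDesign(K=max(curves.times), formula=formula)
    hazards = hazards_from_survival(table)
    gamma = fit_msm(hazards, design)
    cov = msm_variance(gamma, design, table, curves.ic_matrix())
    return MSMResult(design=design, gamma=gamma, covariance=cov, hazards=hazards)
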