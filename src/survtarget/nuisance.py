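"""Exposure, censoring, and event/iterated-expectation model fitting.

The exposure model gives g_A(a | L1) = P(A = a | L1). The censoring model at
interval t gives P(C_t = 1 | A, covariate history, C_{t-1} = 0, Y_{t-1} = 0)
and is fitted on that risk set. The event model at interval j is fitted on
the risk set {C_j = 0, Y_{j-1} = 0}; at the target horizon its response is
the observed event indicator, and at earlier intervals it is the previous
backward step's updated (fractional) prediction.

``lookback`` controls how many of the most recent time-varying covariate
blocks enter a model in addition to the exposure and all baseline
covariates; ``None`` uses the full history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import WideSurvivalData
from .learners import (
    ConstantModel,
    FittedProbabilityModel,
    LogisticLearner,
    MultinomialLogisticLearner,
    _MultinomialModel,
)

logger = logging.getLogger(__name__)

__all__ = ["NuisanceFits", "covariate_frame", "fit_exposure", "fit_censoring", "fit_outcome_step"]


def covariate_frame(
    data: WideSurvivalData,
    t: int,
    lookback: int | None = None,
    exposure_level: int | None = None,
    include_exposure: bool = True,
) -> pd.DataFrame:
    """Assemble the covariate rows used by models at interval ``t``.

    Columns: exposure (observed, or fixed to ``exposure_level`` for
    counterfactual prediction), all baseline covariates, and the time-varying
    blocks for intervals max(2, t - lookback + 1)..t.
    """
    parts = {}
    if include_exposure:
        if exposure_level is None:
            parts["__A__"] = np.asarray(data.exposure, dtype=float)
        else:
            parts["__A__"] = np.full(data.n, float(exposure_level))
    frame = pd.DataFrame(parts, index=range(data.n))
    frame = pd.concat([frame, data.baseline.reset_index(drop=True)], axis=1)
    if data.tv_covariates:
        first = 2 if lookback is None else max(2, t - lookback + 1)
        for s in range(first, t + 1):
            block = data.tv_covariates.get(s)
            if block is not None:
                block = block.reset_index(drop=True)
                block.columns = [f"{c}" for c in block.columns]
                frame = pd.concat([frame, block], axis=1)
    return frame


def fit_exposure(data: WideSurvivalData, learner=None) -> FittedProbabilityModel:
    """Fit P(A = a | L1); binary exposures may use any probability learner.

    Multilevel exposures are fitted with a multinomial logistic model so the
    per-level probabilities sum to one for every subject.
    """
    levels = data.exposure_levels
    if levels.size < 2:
        raise ValueError("degenerate exposure: a single level observed")
    X = data.baseline.reset_index(drop=True)
    if levels.size == 2 and learner is not None and not isinstance(
        learner, MultinomialLogisticLearner
    ):
        return learner.fit(X, (data.exposure == levels.max()).astype(float))
    return MultinomialLogisticLearner().fit(X, np.asarray(data.exposure))


def fit_censoring(
    data: WideSurvivalData,
    t: int,
    lookback: int | None = None,
    learner=None,
) -> FittedProbabilityModel:
    """Fit P(C_t = 1 | A, history) on the risk set {C_{t-1}=0, Y_{t-1}=0}."""
    learner = learner or LogisticLearner()
    mask = data.uncensored_through(t - 1) & ~data.event_before(t)
    if not mask.any():
        raise ValueError(f"empty risk set for the censoring model at t={t}")
    y = data.censor[mask, t - 1]
    if np.all(y == 0):
        logger.warning("no censoring events at t=%d; using a zero-probability model", t)
        return ConstantModel(0.0)
    X = covariate_frame(data, t, lookback)
    return learner.fit(X.loc[mask], y)


def fit_outcome_step(
    data: WideSurvivalData,
    j: int,
    response: np.ndarray,
    lookback: int | None = None,
    learner=None,
) -> FittedProbabilityModel:
    """Fit the event / iterated-expectation model at interval ``j``.

    ``response`` is a length-n vector in [0, 1]; only entries on the risk set
    {C_j = 0, Y_{j-1} = 0} are used. The fitted model predicts for
    counterfactual covariate rows in which the exposure column is set to a.
    """
    learner = learner or LogisticLearner()
    mask = data.uncensored_through(j) & ~data.event_before(j)
    if not mask.any():
        raise ValueError(f"empty risk set for the outcome model at j={j}")
    y = np.asarray(response, dtype=float)[mask]
    if np.isnan(y).any():
        raise ValueError(f"missing responses on the risk set at j={j}")
    if np.all(y == 0):
        logger.warning("all-zero response at j=%d; using a zero-probability model", j)
        return ConstantModel(0.0)
    X = covariate_frame(data, j, lookback)
    return learner.fit(X.loc[mask], y)


@dataclass
class NuisanceFits:
    """Fitted exposure and per-interval censoring models with cached predictions."""

    data: WideSurvivalData
    exposure_model: FittedProbabilityModel
    censoring_models: list[FittedProbabilityModel]
    lookback: int | None = None
    _exposure_cache: dict = field(default_factory=dict, repr=False)
    _censor_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def fit(
        cls,
        data: WideSurvivalData,
        exposure_learner=None,
        censoring_learner=None,
        lookback: int | None = None,
        through: int | None = None,
    ) -> "NuisanceFits":
        through = data.K if through is None else through
        cens = [
            fit_censoring(data, t, lookback, censoring_learner)
            for t in range(1, through + 1)
        ]
        return cls(
            data=data,
            exposure_model=fit_exposure(data, exposure_learner),
            censoring_models=cens,
            lookback=lookback,
        )

    def exposure_prob(self, a: int) -> np.ndarray:
        """P(A = a | L1) per subject."""
        if a not in self._exposure_cache:
            X = self.data.baseline.reset_index(drop=True)
            levels = self.data.exposure_levels
            if isinstance(self.exposure_model, _MultinomialModel):
                p = self.exposure_model.predict_level(X, a)
            else:
                p1 = self.exposure_model.predict(X)
                p = p1 if a == levels.max() else 1.0 - p1
            self._exposure_cache[a] = np.asarray(p, dtype=float)
        return self._exposure_cache[a]

    def censor_prob(self, t: int, a: int) -> np.ndarray:
        """P(C_t = 1 | A = a, history) per subject."""
        if (t, a) not in self._censor_cache:
            X = covariate_frame(self.data, t, self.lookback, exposure_level=a)
            self._censor_cache[(t, a)] = np.asarray(
                self.censoring_models[t - 1].predict(X), dtype=float
            )
        return self._censor_cache[(t, a)]

    def cumulative_uncensored(self, a: int, j: int, gbound: float = 0.0) -> np.ndarray:
        """Product over k <= j of the probability of remaining uncensored.

        Each factor 1 - P(C_k = 1 | .) is floored at ``gbound`` before the
        product is taken, so the result is non-increasing in j and strictly
        positive whenever gbound > 0.
        """
        out = np.ones(self.data.n)
        for k in range(1, j + 1):
            out = out * np.maximum(1.0 - self.censor_prob(k, a), gbound)
        return out
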