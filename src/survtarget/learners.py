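"""Probability learners for the exposure, censoring, and event processes.

All learners fit conditional probabilities and must accept fractional
responses in [0, 1] with observation weights: the backward recursion that
estimates survival at later horizons regresses *predicted probabilities*
from the previous step, not 0/1 events. Parametric fits therefore use
quasi-binomial iteratively reweighted least squares (a logit-link mean
model), delegated to statsmodels GLM.

The stacking ensemble combines a library of such learners with convex
weights chosen to minimise cross-validated squared-error loss (non-negative
least squares on the out-of-fold prediction matrix, then normalisation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "fit_weighted_logistic",
    "FittedProbabilityModel",
    "ConstantModel",
    "LogisticLearner",
    "MeanLearner",
    "SplineLogisticLearner",
    "MultinomialLogisticLearner",
    "SuperLearner",
    "adaptive_folds",
    "default_library",
]


def fit_weighted_logistic(X, y, weights=None, offset=None, tol=1e-10):
    """Quasi-binomial IRLS fit of y in [0,1] on X with optional weights/offset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(
            np.asarray(y, dtype=float),
            np.asarray(X, dtype=float),
            family=sm.families.Binomial(),
            var_weights=None if weights is None else np.asarray(weights, dtype=float),
            offset=None if offset is None else np.asarray(offset, dtype=float),
        )
        return model.fit(tol=tol, maxiter=300)


class FittedProbabilityModel:
    """Interface: ``predict(X) -> probabilities in [0, 1]`` for covariate rows."""

    def predict(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class ConstantModel(FittedProbabilityModel):
    value: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.full(len(X), float(np.clip(self.value, 0.0, 1.0)))


class _GLMModel(FittedProbabilityModel):
    def __init__(self, result, design_fn):
        self.result = result
        self.params = np.asarray(result.params)
        self._design_fn = design_fn

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        D = self._design_fn(X)
        return np.clip(np.asarray(self.result.predict(D)), 0.0, 1.0)


def _weighted_mean(y, w):
    y = np.asarray(y, dtype=float)
    if w is None:
        return float(np.mean(y)) if y.size else 0.0
    w = np.asarray(w, dtype=float)
    return float(np.average(y, weights=w)) if w.sum() > 0 else float(np.mean(y))


@dataclass
class MeanLearner:
    """Intercept-only model: predicts the (weighted) mean response."""

    name: str = "mean"

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> FittedProbabilityModel:
        return ConstantModel(_weighted_mean(y, sample_weight))


def _continuous_columns(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if X[c].nunique(dropna=True) > 2]


@dataclass
class LogisticLearner:
    """Logistic regression, optionally with two-way interactions and squares.

    ``interactions`` adds all pairwise products of covariate columns (with
    binary covariates this saturates the design); ``squares`` adds squared
    terms for continuous columns.
    """

    interactions: bool = False
    squares: bool = False
    name: str = "logistic"

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        names = list(X.columns)
        for c in names:
            cols.append(X[c].to_numpy(dtype=float))
        if self.interactions:
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    cols.append(
                        X[names[i]].to_numpy(dtype=float) * X[names[j]].to_numpy(dtype=float)
                    )
        if self.squares:
            for c in _continuous_columns(X):
                cols.append(X[c].to_numpy(dtype=float) ** 2)
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> FittedProbabilityModel:
        y = np.asarray(y, dtype=float)
        if np.all(y == y[0]) if y.size else True:
            return ConstantModel(y[0] if y.size else 0.0)
        D = self._design(X)
        # drop collinear columns (e.g. a constant covariate next to the intercept)
        keep = _independent_columns(D)
        res = fit_weighted_logistic(D[:, keep], y, weights=sample_weight)
        return _GLMModel(res, lambda Z, k=keep: self._design(Z)[:, k])


def _independent_columns(D: np.ndarray) -> list[int]:
    keep: list[int] = []
    for j in range(D.shape[1]):
        cand = D[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return keep


def _spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    cols = [x, x**2, x**3]
    for k in knots:
        cols.append(np.clip(x - k, 0.0, None) ** 3)
    return np.column_stack(cols)


@dataclass
class SplineLogisticLearner:
    """Additive logistic model with truncated-power cubic splines.

    Continuous covariates get a cubic basis with interior knots at quantiles;
    binary covariates enter linearly. A light-weight generalized additive
    model for the learner library.
    """

    n_knots: int = 3
    name: str = "spline"
    _knots: dict[str, np.ndarray] = field(default_factory=dict)

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        for c in X.columns:
            x = X[c].to_numpy(dtype=float)
            if c in self._knots:
                cols.append(_spline_basis(x, self._knots[c]))
            else:
                cols.append(x[:, None])
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> FittedProbabilityModel:
        y = np.asarray(y, dtype=float)
        if np.all(y == y[0]) if y.size else True:
            return ConstantModel(y[0] if y.size else 0.0)
        self._knots = {}
        for c in _continuous_columns(X):
            qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
            self._knots[c] = np.unique(np.quantile(X[c].to_numpy(dtype=float), qs))
        D = self._design(X)
        keep = _independent_columns(D)
        res = fit_weighted_logistic(D[:, keep], y, weights=sample_weight)
        return _GLMModel(res, lambda Z, k=keep: self._design(Z)[:, k])


class _MultinomialModel(FittedProbabilityModel):
    def __init__(self, clf, classes):
        self.clf = clf
        self.classes = list(classes)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Matrix of per-level probabilities, columns ordered as ``self.classes``."""
        return self.clf.predict_proba(np.asarray(X, dtype=float))

    def predict_level(self, X: pd.DataFrame, level) -> np.ndarray:
        return self.predict(X)[:, self.classes.index(level)]


@dataclass
class MultinomialLogisticLearner:
    """Unpenalised multinomial logistic regression for multilevel exposures."""

    name: str = "multinomial"

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> FittedProbabilityModel:
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("degenerate exposure: a single level observed")
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        clf.fit(np.asarray(X, dtype=float), y, sample_weight=sample_weight)
        return _MultinomialModel(clf, clf.classes_)


def adaptive_folds(n_effective: int) -> int:
    """Map effective sample size to a cross-validation fold count.

    Small samples get more folds so that every training split is still large
    enough to fit the library; large samples get fewer folds to bound cost.
    """
    if n_effective < 30:
        raise ValueError("too few observations for cross-validated stacking (< 30)")
    if n_effective <= 500:
        return 10
    if n_effective <= 5000:
        return 5
    return 2


class _StackedModel(FittedProbabilityModel):
    def __init__(self, models, weights, names):
        self.models = models
        self.weights = np.asarray(weights, dtype=float)
        self.names = names

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = np.column_stack([m.predict(X) for m in self.models])
        return np.clip(Z @ self.weights, 0.0, 1.0)


@dataclass
class SuperLearner:
    """Cross-validated stacking of probability learners under squared-error loss.

    The combined predictor is a convex combination of the library members'
    predictions; the weights are obtained by non-negative least squares of
    the response on the out-of-fold prediction matrix, normalised to sum to
    one. A learner that fails on any fold is dropped with a warning; if every
    learner fails the ensemble falls back to the intercept-only mean.
    """

    library: list = field(default_factory=lambda: default_library())
    folds: int | str = "adaptive"
    random_state: int = 0
    name: str = "super-learner"
    weights_: np.ndarray | None = None
    learner_names_: list[str] | None = None
    n_folds_: int | None = None

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> FittedProbabilityModel:
        if not self.library:
            raise ValueError("empty learner library")
        y = np.asarray(y, dtype=float)
        n = len(y)
        k = self.folds if isinstance(self.folds, int) else adaptive_folds(n)
        if k < 2:
            raise ValueError("stacking requires at least 2 folds")
        self.n_folds_ = k
        X = X.reset_index(drop=True)
        oof = np.full((n, len(self.library)), np.nan)
        ok = [True] * len(self.library)
        for train, test in KFold(k, shuffle=True, random_state=self.random_state).split(X):
            for j, learner in enumerate(self.library):
                if not ok[j]:
                    continue
                try:
                    m = learner.fit(
                        X.iloc[train],
                        y[train],
                        None if sample_weight is None else np.asarray(sample_weight)[train],
                    )
                    oof[test, j] = m.predict(X.iloc[test])
                except Exception as exc:  # drop the learner, keep the ensemble
                    ok[j] = False
                    logger.warning("stacking: learner %r dropped (%s)", learner.name, exc)
        kept = [j for j in range(len(self.library)) if ok[j]]
        if not kept:
            logger.warning("stacking: all learners failed; falling back to the mean")
            self.weights_ = np.array([1.0])
            self.learner_names_ = ["mean"]
            return MeanLearner().fit(X, y, sample_weight)
        Z = oof[:, kept]
        w_obs = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        sw = np.sqrt(w_obs)
        coef, _ = nnls(Z * sw[:, None], y * sw)
        if coef.sum() <= 0:
            coef = np.ones(len(kept))
        weights = coef / coef.sum()
        models = [self.library[j].fit(X, y, sample_weight) for j in kept]
        self.weights_ = weights
        self.learner_names_ = [self.library[j].name for j in kept]
        return _StackedModel(models, weights, self.learner_names_)


def default_library() -> list:
    """Mean, main-terms logistic, logistic with interactions and squares, splines."""
    return [
        MeanLearner(),
        LogisticLearner(name="logistic"),
        LogisticLearner(interactions=True, squares=True, name="logistic-int-sq"),
        SplineLogisticLearner(name="spline"),
    ]
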