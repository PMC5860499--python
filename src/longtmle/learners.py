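"""Candidate prediction algorithms for the stacking ensemble.

Every learner maps a design table to predicted probabilities in [0, 1] and
supports (a) nonnegative observation weights and (b) *fractional* outcomes in
[0, 1] — the sequential outcome regressions regress previously predicted
values, so a quasi-Bernoulli likelihood is required.  Fractional outcomes are
handled exactly by expanding each observation into a pair of 0/1 rows with
weights ``w*(1-y)`` and ``w*y``; the weighted binary log-likelihood of the
expanded data equals the quasi-Bernoulli log-likelihood of the original.

The default library is intercept-only, main-terms logistic, logistic with
all pairwise interactions, and an L1-penalized logistic — a dependency-light
core of the usual candidate set.  Anything with the same three-method
surface (``fit(X, y, weights)`` / ``predict(X)`` / ``clone()``) can be
plugged in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from .exceptions import ConfigError

PRED_BOUND = 1e-4  # numerical floor/ceiling on predicted probabilities


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative learner description used in run configs."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def build(self) -> "Learner":
        try:
            factory = _REGISTRY[self.name]
        except KeyError:
            raise ConfigError(
                f"unknown learner {self.name!r}; known: {sorted(_REGISTRY)}"
            ) from None
        return factory(**self.hyperparameters)


def _expand_fractional(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Exact two-row Bernoulli expansion of fractional outcomes."""
    frac = (y > 0) & (y < 1)
    if not frac.any():
        return X, y.astype(int), w
    X2 = np.vstack([X, X[frac]])
    y2 = np.concatenate([np.where(frac, 1.0, y), np.zeros(frac.sum())])
    w2 = np.concatenate([np.where(frac, w * y, w), (w * (1.0 - y))[frac]])
    keep = w2 > 0
    return X2[keep], y2[keep].astype(int), w2[keep]


class Learner:
    """Base class; subclasses implement ``_fit`` and ``_predict``."""

    name = "base"

    def fit(self, X, y, weights=None) -> "Learner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ConfigError("negative observation weights")
        keep = w > 0
        X, y, w = X[keep], y[keep], w[keep]
        if len(y) == 0:
            raise ConfigError("no observations with positive weight")
        self._mean = float(np.average(y, weights=w))
        self._degenerate = np.allclose(y, y[0]) or X.shape[1] == 0
        if not self._degenerate:
            self._fit(X, y, w)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if getattr(self, "_degenerate", False):
            p = np.full(len(X), self._mean)
        else:
            p = self._predict(X)
        return np.clip(p, PRED_BOUND, 1.0 - PRED_BOUND)

    def clone(self) -> "Learner":
        raise NotImplementedError

    def _fit(self, X, y, w):  # pragma: no cover - abstract
        raise NotImplementedError

    def _predict(self, X):  # pragma: no cover - abstract
        raise NotImplementedError


class InterceptLearner(Learner):
    """Weighted outcome mean, ignoring all covariates."""

    name = "intercept"

    def _fit(self, X, y, w):
        pass

    def _predict(self, X):
        return np.full(len(X), self._mean)

    def clone(self):
        return InterceptLearner()


class _LogisticBase(Learner):
    """Shared machinery for the scikit-learn logistic learners."""

    def _make_model(self) -> LogisticRegression:
        raise NotImplementedError

    def _transform(self, X, fit: bool):
        return X

    def _fit(self, X, y, w):
        X = self._transform(X, fit=True)
        self._scaler = StandardScaler()
        Xs = self._scaler.fit_transform(X)
        Xe, ye, we = _expand_fractional(Xs, y, w)
        if len(np.unique(ye)) < 2:
            self._degenerate = True
            return
        self._model = self._make_model()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit(Xe, ye, sample_weight=we)

    def _predict(self, X):
        Xs = self._scaler.transform(self._transform(X, fit=False))
        return self._model.predict_proba(Xs)[:, 1]


class MainTermsLogistic(_LogisticBase):
    """Unpenalized logistic regression with main terms only."""

    name = "logit_main"

    def _make_model(self):
        return LogisticRegression(penalty=None, max_iter=1000)

    def clone(self):
        return MainTermsLogistic()


class InteractionLogistic(_LogisticBase):
    """Logistic regression with all two-way interactions in the predictor."""

    name = "logit_interact"

    def _transform(self, X, fit):
        if fit:
            self._poly = PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)
            return self._poly.fit_transform(X)
        return self._poly.transform(X)

    def _make_model(self):
        # tiny ridge keeps the expanded design identifiable
        return LogisticRegression(penalty="l2", C=1e4, max_iter=1000)

    def clone(self):
        return InteractionLogistic()


class L1Logistic(_LogisticBase):
    """L1-penalized logistic regression (lasso-type variable selection)."""

    name = "logit_l1"

    def __init__(self, C: float = 1.0):
        self.C = C

    def _make_model(self):
        return LogisticRegression(penalty="l1", C=self.C, solver="liblinear", max_iter=1000)

    def clone(self):
        return L1Logistic(C=self.C)


class SaturatedLearner(Learner):
    """Weighted cell means over unique covariate rows.

    With discrete covariates this is the fully saturated (nonparametric)
    regression: predictions equal empirical conditional frequencies exactly.
    Unseen cells at prediction time fall back to the overall weighted mean.
    Cell means are *not* clipped, so degenerate cells keep their exact 0/1
    values (required for the nonparametric oracle identities).
    """

    name = "saturated"

    def fit(self, X, y, weights=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
        keep = w > 0
        X, y, w = X[keep], y[keep], w[keep]
        self._mean = float(np.average(y, weights=w))
        self._cells = {}
        if X.shape[1] > 0:
            df = pd.DataFrame(X)
            df["_y"], df["_w"] = y * w, w
            g = df.groupby(list(range(X.shape[1])), sort=False)[["_y", "_w"]].sum()
            for key, val in (g["_y"] / g["_w"]).items():
                self._cells[key if isinstance(key, tuple) else (key,)] = val
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.array([self._cells.get(tuple(row), self._mean) for row in X])

    def clone(self):
        return SaturatedLearner()


_REGISTRY = {
    "intercept": InterceptLearner,
    "logit_main": MainTermsLogistic,
    "logit_interact": InteractionLogistic,
    "logit_l1": L1Logistic,
    "saturated": SaturatedLearner,
}


def default_library() -> list[LearnerSpec]:
    """Intercept, main-terms, pairwise-interaction and L1 logistic candidates."""
    return [
        LearnerSpec("intercept"),
        LearnerSpec("logit_main"),
        LearnerSpec("logit_interact"),
        LearnerSpec("logit_l1"),
    ]


def build_library(specs) -> list[Learner]:
    """Instantiate learners from specs (strings are bare learner names)."""
    out = []
    for s in specs:
        if isinstance(s, str):
            s = LearnerSpec(s)
        if isinstance(s, LearnerSpec):
            out.append(s.build())
        elif isinstance(s, Learner):
            out.append(s.clone())
        else:
            raise ConfigError(f"cannot interpret learner spec: {s!r}")
    return out
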