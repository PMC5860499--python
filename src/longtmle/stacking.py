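"""Cross-validated convex stacking (super learner) of candidate learners.

The ensemble weight vector minimizes the cross-validated negative
(quasi-)Bernoulli log-likelihood of the stacked held-out predictions over
the probability simplex.  The loss is convex in the weights, so the optimum
is found by constrained minimization; every vertex of the simplex is
feasible, hence the ensemble's CV loss never exceeds the best single
candidate's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .exceptions import ConfigError
from .learners import Learner, build_library

_LOSS_EPS = 1e-12


def log_loss(y: np.ndarray, p: np.ndarray, w: np.ndarray) -> float:
    """Weighted mean negative Bernoulli log-likelihood (valid for y in [0,1])."""
    p = np.clip(p, _LOSS_EPS, 1.0 - _LOSS_EPS)
    ll = y * np.log(p) + (1.0 - y) * np.log(1.0 - p)
    return float(-np.sum(w * ll) / np.sum(w))


def _make_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded fold labels, stratified on the binarized outcome where possible."""
    n = len(y)
    labels = np.empty(n, dtype=int)
    strata = [np.where(y < 0.5)[0], np.where(y >= 0.5)[0]]
    if min(len(s) for s in strata if len(s)) < folds:
        strata = [np.arange(n)]
    for idx in strata:
        if len(idx) == 0:
            continue
        perm = rng.permutation(idx)
        labels[perm] = np.arange(len(perm)) % folds
    return labels


@dataclass
class EnsembleFit:
    """A fitted convex stack of candidate learners."""

    learner_fits: list[Learner]
    weights: np.ndarray
    cv_losses: np.ndarray | None  # per-learner CV loss (None for 1 candidate)
    ensemble_cv_loss: float | None
    folds: int
    seed: int

    def predict(self, X) -> np.ndarray:
        preds = np.column_stack([lrn.predict(X) for lrn in self.learner_fits])
        return preds @ self.weights


def cv_superlearner(
    library,
    X,
    y,
    weights=None,
    folds: int = 10,
    seed: int = 0,
) -> EnsembleFit:
    """Fit the convex stacking ensemble.

    ``library`` is a list of learner specs / learners; ``y`` may be
    fractional in [0, 1]; rows with weight 0 are dropped from both fitting
    and the CV loss.  Deterministic given ``seed``.  A single-candidate
    library short-circuits to weight 1 on that candidate with no CV pass.
    """
    learners = build_library(library)
    if len(learners) == 0:
        raise ConfigError("empty learner library")
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    keep = w > 0
    X, y, w = X[keep], y[keep], w[keep]
    if len(y) == 0:
        raise ConfigError("no observations with positive weight")

    if len(learners) == 1:
        fit = learners[0].clone().fit(X, y, w)
        return EnsembleFit([fit], np.array([1.0]), None, None, folds, seed)

    if len(y) < folds:
        raise ConfigError(f"{len(y)} rows is fewer than {folds} folds")

    rng = np.random.default_rng(seed)
    fold_of = _make_folds(y, folds, rng)

    n, L = len(y), len(learners)
    Z = np.empty((n, L))
    for k in range(folds):
        test = fold_of == k
        train = ~test
        for j, lrn in enumerate(learners):
            Z[test, j] = lrn.clone().fit(X[train], y[train], w[train]).predict(X[test])

    cv_losses = np.array([log_loss(y, Z[:, j], w) for j in range(L)])
    if not np.isfinite(cv_losses).all():
        raise ConfigError("non-finite cross-validated loss")

    def objective(alpha):
        return log_loss(y, Z @ alpha, w)

    res = minimize(
        objective,
        x0=np.full(L, 1.0 / L),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * L,
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
        options={"ftol": 1e-8, "maxiter": 500},
    )
    alpha = np.clip(res.x, 0.0, None)
    alpha /= alpha.sum()
    best = int(np.argmin(cv_losses))
    if objective(alpha) > cv_losses[best]:
        # optimizer failed to beat the best vertex; the vertex is feasible
        alpha = np.zeros(L)
        alpha[best] = 1.0
    ens_loss = objective(alpha)

    fits = [lrn.clone().fit(X, y, w) for lrn in learners]
    return EnsembleFit(fits, alpha, cv_losses, ens_loss, folds, seed)


def fit_ensemble(library, X, y, weights=None, folds: int = 10, seed: int = 0) -> EnsembleFit:
    """Stacking fit that degrades gracefully on tiny fitting sets.

    Late sequential-regression steps and late-period treatment models can be
    left with only a handful of at-risk followers.  Fold counts are capped at
    half the number of contributing rows, and with fewer than 4 rows the fit
    collapses to the intercept learner (cross-validating a model comparison
    on 2-3 subjects is meaningless).
    """
    y = np.asarray(y, dtype=float)
    n = len(y) if weights is None else int((np.asarray(weights) > 0).sum())
    if n < 4:
        return cv_superlearner(["intercept"], X, y, weights, folds=2, seed=seed)
    eff = max(2, min(folds, n // 2))
    return cv_superlearner(library, X, y, weights, folds=eff, seed=seed)
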