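"""Naive, IPTW, ICE g-computation and longitudinal TMLE estimators.

All four target the intervention-specific mean

    psi(d, t*) = E[Y_{t*}^d],

the counterfactual cumulative probability of live discharge by the end of
period ``t*`` had everyone followed regime ``d``, with death as a competing
absorbing event.

* ``naive_estimate``      — outcome proportion among observed regime followers.
* ``iptw_estimate``       — stabilized Horvitz–Thompson ratio with weights
                            I(followed d through t*-1) / prod_t g_t.
* ``ice_gcomp_estimate``  — iterated-conditional-expectation g-computation:
                            sequentially regress the outcome (then the previous
                            step's predictions) on shorter histories among
                            at-risk followers, predict under the regime, and
                            finally average over the empirical baseline law.
* ``tmle_estimate``       — the same recursion with a one-parameter logistic
                            fluctuation after every regression (intercept
                            submodel with offset logit(Qbar) and weights
                            I/cumulative-g), yielding double robustness and
                            influence-curve-based Wald intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import EstimationError
from .panel import PanelData, at_risk_mask, history_matrix
from .regimes import Regime, counterfactual_assignment, follow_indicator
from .stacking import fit_ensemble
from .treatment import TreatmentMechanism, cumulative_g, fit_treatment_mechanism, min_cumulative_g

Q_BOUND = 1e-4  # clip for Qbar predictions before taking logits
EPS_CAP = 18.0  # cap on the fluctuation parameter, logit scale
_DET_TOL = 1e-12  # values this close to 0/1 are treated as deterministic


@dataclass
class EstimateResult:
    """A single estimate of psi(d, t*) with inference where available."""

    psi_hat: float
    estimator: str
    regime_label: str
    t_star: int
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ic: np.ndarray | None = None
    n_followers: int = 0
    min_cum_g: float | None = None

    def __post_init__(self):
        if self.se is not None and self.ci_low is None:
            self.ci_low = float(np.clip(self.psi_hat - 1.96 * self.se, 0.0, 1.0))
            self.ci_high = float(np.clip(self.psi_hat + 1.96 * self.se, 0.0, 1.0))


@dataclass
class SequentialFits:
    """Initial and updated sequential regression values per step."""

    qbar_init: dict[int, np.ndarray] = field(default_factory=dict)
    qbar_updated: dict[int, np.ndarray] = field(default_factory=dict)
    epsilons: dict[int, float] = field(default_factory=dict)
    scores: dict[int, float] = field(default_factory=dict)


def _followers(panel: PanelData, regime: Regime, t_star: int) -> np.ndarray:
    return follow_indicator(panel, regime, t_star - 1)


def naive_estimate(panel: PanelData, regime: Regime, t_star: int) -> EstimateResult:
    """Simple proportion of discharge by t* among observed regime followers."""
    foll = _followers(panel, regime, t_star) == 1
    n_f = int(foll.sum())
    if n_f == 0:
        raise EstimationError(f"no followers of {regime.label!r} through t*={t_star}")
    y = panel.y(t_star)[foll]
    psi = float(y.mean())
    ic = y - psi
    se = float(ic.std(ddof=0) / np.sqrt(n_f))
    return EstimateResult(
        psi_hat=psi, estimator="naive", regime_label=regime.label, t_star=t_star,
        se=se, ic=ic, n_followers=n_f,
    )


def iptw_estimate(
    panel: PanelData,
    regime: Regime,
    t_star: int,
    mechanism: TreatmentMechanism,
    g_lower_bound: float | None = None,
) -> EstimateResult:
    """Stabilized Horvitz–Thompson ratio estimator with IC-based inference."""
    foll = _followers(panel, regime, t_star)
    n_f = int(foll.sum())
    if n_f == 0:
        raise EstimationError(f"no followers of {regime.label!r} through t*={t_star}")
    cg = cumulative_g(mechanism, t_star, g_lower_bound)
    w = foll / cg
    if not np.isfinite(w).all() or w.sum() <= 0:
        raise EstimationError("degenerate IPTW weights")
    y = panel.y(t_star)
    psi = float(np.sum(w * y) / np.sum(w))
    ic = w * (y - psi) / w.mean()
    se = float(ic.std(ddof=0) / np.sqrt(panel.n))
    return EstimateResult(
        psi_hat=psi, estimator="iptw", regime_label=regime.label, t_star=t_star,
        se=se, ic=ic, n_followers=n_f,
        min_cum_g=min_cumulative_g(mechanism, panel, regime, t_star),
    )


def tmle_update_step(
    qbar_init: np.ndarray,
    pseudo_outcome: np.ndarray,
    weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """One-parameter logistic fluctuation of the current Qbar fit.

    Solves the weighted score  sum_i w_i (y_i - expit(logit(q_i) + eps)) = 0
    for the intercept ``eps`` of the submodel logit(Q1) = logit(Q) + eps, and
    returns the updated predictions for every subject.  Entries of ``q``
    that are exactly 0 or 1 are deterministic (already-resolved subjects) and
    are left untouched.  With no positive weight, eps = 0 by convention.
    """
    q = np.asarray(qbar_init, dtype=float)
    y = np.asarray(pseudo_outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    movable = (q > _DET_TOL) & (q < 1.0 - _DET_TOL)
    lq = logit(np.clip(q, Q_BOUND, 1.0 - Q_BOUND))
    active = (w > 0) & movable

    def updated(eps: float) -> np.ndarray:
        out = q.copy()
        out[movable] = expit(lq[movable] + eps)
        return out

    if not active.any():
        return 0.0, updated(0.0)

    def score(eps: float) -> float:
        return float(np.sum(w[active] * (y[active] - expit(lq[active] + eps))))

    lo, hi = score(-EPS_CAP), score(EPS_CAP)
    if lo <= 0.0:  # even eps = -cap cannot push predictions low enough
        warnings.warn("fluctuation parameter capped at -18 on the logit scale")
        return -EPS_CAP, updated(-EPS_CAP)
    if hi >= 0.0:
        warnings.warn("fluctuation parameter capped at +18 on the logit scale")
        return EPS_CAP, updated(EPS_CAP)
    eps = brentq(score, -EPS_CAP, EPS_CAP, xtol=1e-12)
    # Newton polish: the score is monotone with derivative -sum w q'(1-q')
    for _ in range(5):
        s = score(eps)
        if abs(s) < 1e-11:
            break
        p = expit(lq[active] + eps)
        deriv = -np.sum(w[active] * p * (1.0 - p))
        if deriv == 0.0:
            break
        eps -= s / deriv
    return float(eps), updated(eps)


def _deterministic_values(panel: PanelData, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Masks of subjects already discharged / dead before period ``t``."""
    discharged = panel.y(t - 1) == 1
    dead = panel.m(t - 1) == 1
    return discharged, dead


def _prediction_design(
    panel: PanelData, regime: Regime, t: int, markov_order
) -> np.ndarray:
    """History through ``t`` with constrained treatments set to the regime."""
    X = history_matrix(panel, t, markov_order, include_treatment_at_t=True).copy()
    for col in X.columns:
        if col.startswith("A"):
            s = int(col[1:])
            ca = counterfactual_assignment(regime, panel, s)
            vals = X[col].to_numpy(dtype=float)
            constrained = ~(ca.unconstrained | ca.post_event)
            vals[constrained] = ca.required[constrained]
            X[col] = vals
    return X.to_numpy()


def _sequential_recursion(
    panel: PanelData,
    regime: Regime,
    t_star: int,
    library,
    folds: int,
    seed: int,
    markov_order,
    mechanism: TreatmentMechanism | None,
    g_lower_bound: float | None,
    update: bool,
) -> tuple[np.ndarray, SequentialFits]:
    """Shared ICE recursion; with ``update`` the TMLE fluctuation is inserted."""
    n = panel.n
    fits = SequentialFits()
    current = panel.y(t_star).astype(float)  # Qbar_{t*+1} := Y_{t*}
    fits.qbar_updated[t_star + 1] = current
    for t in range(t_star, 0, -1):
        risk_prev = at_risk_mask(panel, t - 1) == 1
        foll_prev = follow_indicator(panel, regime, t - 1) == 1
        fit_set = risk_prev & foll_prev
        if not fit_set.any():
            raise EstimationError(
                f"empty fitting set at sequential step t={t} for {regime.label!r}"
            )
        X_fit = history_matrix(
            panel, t - 1, markov_order, include_treatment_at_t=True
        ).to_numpy()
        ens = fit_ensemble(
            library, X_fit[fit_set], current[fit_set], folds=folds, seed=seed + 1000 + t
        )
        X_pred = _prediction_design(panel, regime, t - 1, markov_order)
        pred = ens.predict(X_pred)
        discharged, dead = _deterministic_values(panel, t)
        q_init = np.where(discharged, 1.0, np.where(dead, 0.0, pred))
        fits.qbar_init[t] = q_init
        if update:
            foll = follow_indicator(panel, regime, t - 1)
            cg = cumulative_g(mechanism, t, g_lower_bound)
            w = foll / cg
            eps, q_upd = tmle_update_step(q_init, current, w)
            fits.epsilons[t] = eps
            fits.scores[t] = float(np.sum(w * (current - q_upd)))
        else:
            q_upd = q_init
        fits.qbar_updated[t] = q_upd
        current = q_upd
    return current, fits


def _no_constrained_periods(regime: Regime, t_star: int) -> bool:
    return all(not regime.is_constrained(t) for t in range(t_star))


def _trivial_result(panel, regime, t_star, estimator) -> tuple[EstimateResult, SequentialFits]:
    """With no constrained period before t*, everyone follows and psi is the
    plain mean of Y_{t*}; the IC collapses to Y - psi."""
    y = panel.y(t_star)
    psi = float(y.mean())
    ic = y - psi
    se = float(ic.std(ddof=0) / np.sqrt(panel.n))
    res = EstimateResult(
        psi_hat=psi, estimator=estimator, regime_label=regime.label, t_star=t_star,
        se=None if estimator == "gcomp" else se,
        ic=None if estimator == "gcomp" else ic,
        n_followers=panel.n, min_cum_g=1.0,
    )
    return res, SequentialFits()


def ice_gcomp_estimate(
    panel: PanelData,
    regime: Regime,
    t_star: int,
    library=("logit_main",),
    folds: int = 10,
    seed: int = 0,
    markov_order: int | str = "full",
) -> tuple[EstimateResult, SequentialFits]:
    """Sequential-regression g-computation estimate (no confidence interval:
    no influence-function-based variance is available without targeting)."""
    if _no_constrained_periods(regime, t_star):
        return _trivial_result(panel, regime, t_star, "gcomp")
    qbar1, fits = _sequential_recursion(
        panel, regime, t_star, library, folds, seed, markov_order,
        mechanism=None, g_lower_bound=None, update=False,
    )
    psi = float(qbar1.mean())
    foll = _followers(panel, regime, t_star)
    res = EstimateResult(
        psi_hat=psi, estimator="gcomp", regime_label=regime.label, t_star=t_star,
        n_followers=int(foll.sum()),
    )
    return res, fits


def tmle_estimate(
    panel: PanelData,
    regime: Regime,
    t_star: int,
    mechanism: TreatmentMechanism | None = None,
    library=("logit_main",),
    folds: int = 10,
    seed: int = 0,
    markov_order: int | str = "full",
    g_library=("logit_main",),
    g_markov_order: int | str = 2,
    g_lower_bound: float | None = None,
) -> tuple[EstimateResult, SequentialFits]:
    """Longitudinal TMLE with influence-curve Wald intervals.

    The fluctuation is refit after every sequential regression (one scalar
    per step).  The influence curve is

        IC_i = sum_{t=1}^{t*} [I_i(t-1) / g_{0:t-1,i}] (Q1_{t+1,i} - Q1_{t,i})
               + Q1_{1,i} - psi_hat,

    with Q1_{t*+1} := Y_{t*}; its empirical mean is zero because each
    fluctuation solves the corresponding weighted score.
    """
    if _no_constrained_periods(regime, t_star):
        return _trivial_result(panel, regime, t_star, "tmle")
    if mechanism is None:
        mechanism = fit_treatment_mechanism(
            panel, regime, t_star, library=g_library, folds=folds, seed=seed,
            markov_order=g_markov_order,
        )
    qbar1, fits = _sequential_recursion(
        panel, regime, t_star, library, folds, seed, markov_order,
        mechanism=mechanism, g_lower_bound=g_lower_bound, update=True,
    )
    psi = float(qbar1.mean())
    ic = qbar1 - psi
    for t in range(1, t_star + 1):
        foll = follow_indicator(panel, regime, t - 1)
        w = foll / cumulative_g(mechanism, t, g_lower_bound)
        ic = ic + w * (fits.qbar_updated[t + 1] - fits.qbar_updated[t])
    se = float(ic.std(ddof=0) / np.sqrt(panel.n))
    foll_star = _followers(panel, regime, t_star)
    res = EstimateResult(
        psi_hat=psi, estimator="tmle", regime_label=regime.label, t_star=t_star,
        se=se, ic=ic, n_followers=int(foll_star.sum()),
        min_cum_g=min_cumulative_g(mechanism, panel, regime, t_star),
    )
    return res, fits


def survival_curve(
    panel: PanelData,
    regimes: list[Regime],
    estimators=("tmle",),
    t_range=None,
    library=("logit_main",),
    g_library=("logit_main",),
    folds: int = 10,
    seed: int = 0,
    markov_order: int | str = "full",
    g_markov_order: int | str = 2,
    g_lower_bound: float | None = None,
    ic_collector: dict | None = None,
) -> pd.DataFrame:
    """Counterfactual cumulative-incidence table per (regime, day, estimator).

    Treatment mechanisms are fit once per regime (at the largest requested
    day) and re-used for every earlier day; the output has one row per
    combination with columns regime, t_star, estimator, psi, se, ci_low,
    ci_high, n_followers, min_cum_g.  When a dict is passed as
    ``ic_collector`` the per-subject influence-curve values of every
    estimator that has them are stored under ``(regime, t_star, estimator)``.
    """
    if isinstance(estimators, str):
        estimators = (estimators,)
    if t_range is None:
        t_range = range(1, panel.T_plus_1 + 1)
    t_range = sorted(t_range)
    rows = []
    needs_g = any(e in ("iptw", "tmle") for e in estimators)
    for regime in regimes:
        mech = None
        if needs_g and not _no_constrained_periods(regime, max(t_range)):
            mech = fit_treatment_mechanism(
                panel, regime, max(t_range), library=g_library, folds=folds,
                seed=seed, markov_order=g_markov_order,
            )
        for t_star in t_range:
            for est in estimators:
                if est == "naive":
                    r = naive_estimate(panel, regime, t_star)
                elif est == "iptw":
                    if _no_constrained_periods(regime, t_star):
                        r, _ = _trivial_result(panel, regime, t_star, "iptw")
                    else:
                        r = iptw_estimate(panel, regime, t_star, mech, g_lower_bound)
                elif est == "gcomp":
                    r, _ = ice_gcomp_estimate(
                        panel, regime, t_star, library, folds, seed, markov_order
                    )
                elif est == "tmle":
                    r, _ = tmle_estimate(
                        panel, regime, t_star, mechanism=mech, library=library,
                        folds=folds, seed=seed, markov_order=markov_order,
                        g_lower_bound=g_lower_bound,
                    )
                else:
                    raise EstimationError(f"unknown estimator {est!r}")
                # naive ICs live on the follower subset only; the IC table
                # keeps the full-cohort curves (iptw / tmle)
                if ic_collector is not None and r.ic is not None and len(r.ic) == panel.n:
                    ic_collector[(regime.label, t_star, est)] = r.ic
                rows.append(
                    {
                        "regime": regime.label,
                        "t_star": t_star,
                        "estimator": est,
                        "psi": r.psi_hat,
                        "se": r.se,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "n_followers": r.n_followers,
                        "min_cum_g": r.min_cum_g,
                    }
                )
    return pd.DataFrame(rows)
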