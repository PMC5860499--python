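"""Treatment-mechanism estimation and cumulative follow probabilities.

For each constrained period ``t`` the mechanism

    g_t = Pr[A_t = d_t(V_t) | followed d through t-1, history]

is fit among the subjects who are still at risk at ``t`` and whose observed
treatments matched the regime through ``t-1``, using the configured Markov
window of recent history (2 periods by default).  Unconstrained
(delayed-start) periods and post-event person-periods contribute g_t = 1, so
subjects keep their weight unchanged after discharge or death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import PositivityError
from .panel import PanelData, at_risk_mask, history_matrix
from .regimes import Regime, counterfactual_assignment, follow_indicator
from .stacking import EnsembleFit, fit_ensemble

G_FLOOR = 1e-4  # numerical floor, distinct from any user-set truncation


@dataclass
class TreatmentMechanism:
    """Per-period fitted probabilities of the regime-required treatment."""

    g: np.ndarray  # (t_star, n): g_t per subject, 1 where unconstrained/post-event
    t_star: int
    markov_order: int | str
    regime_label: str
    fits: list[EnsembleFit | None]

    @property
    def n(self) -> int:
        return self.g.shape[1]


def fit_treatment_mechanism(
    panel: PanelData,
    regime: Regime,
    t_star: int,
    library=("logit_main",),
    folds: int = 10,
    seed: int = 0,
    markov_order: int | str = 2,
) -> TreatmentMechanism:
    """Fit g_t for every period t = 0..t_star-1."""
    if not 1 <= t_star <= panel.T_plus_1:
        raise ValueError(f"t_star={t_star} out of range 1..{panel.T_plus_1}")
    n = panel.n
    g = np.ones((t_star, n))
    fits: list[EnsembleFit | None] = []
    for t in range(t_star):
        if not regime.is_constrained(t):
            fits.append(None)
            continue
        ca = counterfactual_assignment(regime, panel, t)
        risk = at_risk_mask(panel, t) == 1
        foll_prev = follow_indicator(panel, regime, t - 1) == 1
        fit_set = risk & foll_prev
        if not fit_set.any():
            raise PositivityError(
                f"no at-risk followers of {regime.label!r} remain at period {t}"
            )
        X = history_matrix(panel, t, markov_order).to_numpy()
        a_t = panel.a(t)
        ens = fit_ensemble(
            library, X[fit_set], a_t[fit_set], folds=folds, seed=seed + t
        )
        fits.append(ens)
        p1 = ens.predict(X)
        g_t = np.where(ca.required == 1, p1, 1.0 - p1)
        g_t = np.clip(g_t, G_FLOOR, 1.0)
        g_t[ca.post_event] = 1.0
        g[t] = g_t
    return TreatmentMechanism(
        g=g, t_star=t_star, markov_order=markov_order, regime_label=regime.label, fits=fits
    )


def cumulative_g(
    mechanism: TreatmentMechanism,
    t_star: int | None = None,
    lower_bound: float | None = None,
) -> np.ndarray:
    """Per-subject product of g_t over t = 0..t_star-1.

    Each factor is floored at ``lower_bound`` when one is set (user-requested
    truncation; the analysis here follows the policy of truncating only when
    the minimum cumulative follow probability drops below 0.05).
    """
    if t_star is None:
        t_star = mechanism.t_star
    if t_star > mechanism.t_star:
        raise ValueError(f"mechanism only covers periods 0..{mechanism.t_star - 1}")
    g = mechanism.g[:t_star]
    if lower_bound is not None:
        g = np.clip(g, lower_bound, 1.0)
    if (g <= 0).any():
        raise PositivityError("zero treatment probability with no lower bound set")
    return g.prod(axis=0)


def min_cumulative_g(
    mechanism: TreatmentMechanism,
    panel: PanelData,
    regime: Regime,
    t_star: int | None = None,
) -> float:
    """Positivity diagnostic: smallest cumulative g among regime followers."""
    if t_star is None:
        t_star = mechanism.t_star
    cg = cumulative_g(mechanism, t_star)
    foll = follow_indicator(panel, regime, t_star - 1) == 1
    if not foll.any():
        return float("nan")
    return float(cg[foll].min())
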