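"""Discrete toy data-generating processes and brute-force oracles.

These DGPs have a single binary time-varying covariate ``l`` and binary
treatment, with at most 3 periods, so their full joint law is enumerable.
They anchor the nonparametric identity checks: the exhaustive g-computation
sum evaluated on a toy law (or on the empirical distribution of a sampled
panel) is the ground truth every estimator is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EstimationError
from .panel import PanelData
from .regimes import Regime, follow_indicator

_MAX_PATHS = 10**5


@dataclass
class ToyDGP:
    """Explicit-probability-table DGP with binary ``l`` and ``a``.

    Tables are ndarrays with one binary axis per preceding variable in
    causal order (l0, a0, l1, a1, ...):

    * ``p_a[t]``  P(A_t = 1 | at risk, history)      axes (l0,a0,...,l_t)
    * ``p_y[t]``  P(Y_{t+1} = 1 | at risk, history)  axes (l0,a0,...,l_t,a_t)
    * ``p_m[t]``  P(M_{t+1} = 1 | at risk, no discharge at t+1, history),
                  same axes as p_y; ``None`` means no deaths that period
    * ``p_l[t]``  P(L_{t+1} = 1 | still at risk, history), same axes as p_y
    """

    T_plus_1: int
    p_l0: float
    p_a: list[np.ndarray]
    p_y: list[np.ndarray]
    p_m: list[np.ndarray | None]
    p_l: list[np.ndarray]

    def __post_init__(self):
        if 2 ** (2 * self.T_plus_1 + 1) > _MAX_PATHS:
            raise EstimationError("toy DGP support too large to enumerate")

    # -- sampling ---------------------------------------------------------
    def sample(self, n: int, seed: int = 0) -> PanelData:
        """Draw ``n`` subjects; absorbing states applied by construction."""
        rng = np.random.default_rng(seed)
        T = self.T_plus_1 - 1
        hist: list[np.ndarray] = [(rng.random(n) < self.p_l0).astype(int)]
        A = np.zeros((n, T + 1), dtype=int)
        Y = np.zeros((n, T + 1), dtype=int)
        M = np.zeros((n, T), dtype=int)
        L = np.zeros((n, T), dtype=int)
        discharged = np.zeros(n, dtype=bool)
        dead = np.zeros(n, dtype=bool)
        for t in range(T + 1):
            at_risk = ~discharged & ~dead
            a_t = (rng.random(n) < self.p_a[t][tuple(hist)]).astype(int)
            if t >= 1:
                a_t[~at_risk] = A[~at_risk, t - 1]  # carry-forward
            A[:, t] = a_t
            hist.append(a_t)
            y_new = (rng.random(n) < self.p_y[t][tuple(hist)]) & at_risk
            discharged |= y_new
            Y[:, t] = discharged
            if t < T:
                if self.p_m[t] is not None:
                    m_new = (rng.random(n) < self.p_m[t][tuple(hist)]) & at_risk & ~y_new
                    dead |= m_new
                M[:, t] = dead
                at_risk = ~discharged & ~dead
                l_next = (rng.random(n) < self.p_l[t][tuple(hist)]).astype(int)
                l_next[~at_risk] = hist[2 * t][~at_risk]  # carry last l
                L[:, t] = l_next
                hist.append(l_next)
        baseline = pd.DataFrame({"l": hist[0]})
        tv = {"l": L} if T >= 1 else None
        return PanelData.from_arrays(baseline, A, Y, M if T >= 1 else None, tv)

    # -- exact interventional mean ---------------------------------------
    def true_psi(self, regime: Regime, t_star: int) -> float:
        """Exact E[Y_{t*}^d] by enumeration of the intervened-on law.

        Constrained treatments are forced to the regime; unconstrained
        (delayed-start) periods keep the observational treatment draw.
        """

        def rec(t: int, hist: tuple[int, ...]) -> float:
            # hist = (l0, a0, ..., l_t); subject at risk entering period t
            l_t = hist[-1]
            if regime.is_constrained(t):
                req = float(regime.required(t, {"l": np.array([l_t])}, 1)[0])
                a_choices = [(int(req), 1.0)]
            else:
                pa = float(self.p_a[t][hist])
                a_choices = [(1, pa), (0, 1.0 - pa)]
            val = 0.0
            for a, pa_ in a_choices:
                if pa_ == 0.0:
                    continue
                h2 = hist + (a,)
                py = float(self.p_y[t][h2])
                contrib = py  # discharge by t+1 <= t_star implies Y_{t*} = 1
                if t + 1 < t_star:
                    pm = float(self.p_m[t][h2]) if self.p_m[t] is not None else 0.0
                    still = (1.0 - py) * (1.0 - pm)
                    if still > 0.0:
                        pl = float(self.p_l[t][h2])
                        sub = 0.0
                        if pl > 0.0:
                            sub += pl * rec(t + 1, h2 + (1,))
                        if pl < 1.0:
                            sub += (1.0 - pl) * rec(t + 1, h2 + (0,))
                        contrib += still * sub
                val += pa_ * contrib
            return val

        return self.p_l0 * rec(0, (1,)) + (1.0 - self.p_l0) * rec(0, (0,))


def _expand(values, axes: int) -> np.ndarray:
    """Broadcast a per-axis linear score into a full probability table."""
    out = np.zeros((2,) * axes)
    for k, coef in enumerate(values[1:]):
        shape = [1] * axes
        shape[k] = 2
        out = out + coef * np.arange(2).reshape(shape)
    return 1.0 / (1.0 + np.exp(-(values[0] + out)))


def discrete_toy_dgp(n_periods: int = 2) -> ToyDGP:
    """Preset enumerable DGPs (1-3 periods) with time-varying confounding.

    The 1-period version is the hand-workable fixture with
    P(L0=1) = 0.5 and P(Y1=1 | A0=1, L0) = (0.2, 0.6), whose g-formula value
    under "always treat" is 0.5*0.2 + 0.5*0.6 = 0.4 exactly.  The 2- and
    3-period versions confound later treatments with the evolving covariate
    and include a small death hazard.
    """
    if n_periods not in (1, 2, 3):
        raise EstimationError("discrete_toy_dgp supports 1-3 periods")
    p_l0 = 0.5
    # axes order: (l0, a0, l1, a1, l2, a2)
    p_a = [_expand([np.log(0.3 / 0.7), np.log(0.7 / 0.3) - np.log(0.3 / 0.7)], 1)]
    p_y = [np.array([[0.4, 0.2], [0.5, 0.6]])]  # [l0, a0]
    p_m: list[np.ndarray | None] = [None]
    p_l: list[np.ndarray] = []
    if n_periods >= 2:
        p_m[0] = np.full((2, 2), 0.03)
        p_l.append(np.array([[0.3, 0.6], [0.5, 0.8]]))  # P(L1=1 | l0, a0)
        p_a.append(_expand([-0.8, 0.3, 0.4, 1.0], 3))  # (l0, a0, l1)
        p_y.append(_expand([-1.2, 0.2, -0.1, 0.9, -0.5], 4))  # (l0,a0,l1,a1)
        p_m.append(None)
    if n_periods == 3:
        p_m[1] = np.full((2, 2, 2, 2), 0.02)
        p_l.append(_expand([-0.5, 0.2, 0.3, 0.8, 0.4], 4))  # P(L2=1|l0,a0,l1,a1)
        p_a.append(_expand([-0.6, 0.2, 0.3, 0.3, 0.5, 1.0], 5))
        p_y.append(_expand([-1.0, 0.2, -0.1, 0.3, -0.2, 0.8, -0.4], 6))
        p_m.append(None)
    return ToyDGP(
        T_plus_1=n_periods, p_l0=p_l0, p_a=p_a, p_y=p_y, p_m=p_m, p_l=p_l
    )


def gformula_exhaustive(law, regime: Regime, t_star: int) -> float:
    """Brute-force evaluation of the g-computation formula.

    ``law`` is either a :class:`ToyDGP` (the sum runs over the exact joint
    law) or a :class:`PanelData` (the sum runs over the empirical
    distribution: conditional outcome means and covariate-transition
    frequencies among observed regime followers).  This is the oracle the
    estimators are tested against.
    """
    if isinstance(law, ToyDGP):
        return law.true_psi(regime, t_star)
    if isinstance(law, PanelData):
        return _empirical_gformula(law, regime, t_star)
    raise EstimationError(f"cannot enumerate law of type {type(law).__name__}")


def _empirical_gformula(panel: PanelData, regime: Regime, t_star: int) -> float:
    f = panel.frame
    n = panel.n
    foll = [follow_indicator(panel, regime, t) == 1 for t in range(t_star)]
    y_star = panel.y(t_star)

    def value(t: int, members: np.ndarray) -> float:
        # members: at risk at t-1, matching covariate history, following
        # the regime through t-2; returns E[Y_{t*}^d | that cell]
        F = members & foll[t - 1]
        nF = int(F.sum())
        if nF == 0:
            raise EstimationError(
                f"empirical positivity hole at step t={t} for {regime.label!r}"
            )
        if t == t_star:
            return float(y_star[F].mean())
        disch = F & (panel.y(t) == 1)
        dead = F & (panel.m(t) == 1)
        total = disch.sum() / nF  # discharged cells are deterministically 1
        risk = F & ~disch & ~dead
        if risk.any():
            cols = panel.z_cols(t)
            if not regime.is_constrained(t):
                # unconstrained treatments stay random: they join the history
                cols = cols + [f"A{t}"]
            sub = f.loc[risk, cols]
            for _, grp in sub.groupby(cols, sort=False):
                cell = np.zeros(n, dtype=bool)
                cell[grp.index] = True
                total += (len(grp) / nF) * value(t + 1, cell)
        return total

    cols0 = panel.z_cols(0)
    if not regime.is_constrained(0):
        cols0 = cols0 + ["A0"]
    psi = 0.0
    for _, grp in f.groupby(cols0, sort=False):
        cell = np.zeros(n, dtype=bool)
        cell[grp.index] = True
        psi += (len(grp) / n) * value(1, cell)
    return psi
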