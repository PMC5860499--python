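"""Static, delayed-start and dynamic longitudinal treatment regimes.

A regime ``d = (d_0, ..., d_T)`` maps each subject's realized covariate
history to the treatment the rule requires in each period:

* **static** — a fixed 0/1 vector, e.g. "never feed" = (0, ..., 0) or
  "feed from day 3" = (0, 0, 1, ..., 1);
* **delayed start** — early periods are left unconstrained (treatment stays
  whatever it was observed to be) and treatment is required from a given
  period onward, e.g. "feed by day 3" = (A0, A1, 1, ..., 1);
* **dynamic** — the required value is a deterministic function of a current
  time-varying covariate, e.g. "feed on every day off mechanical
  ventilation".

Regimes only assign treatment up to discharge or death: a subject who
followed a regime until their absorbing event counts as following it for the
rest of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import ConfigError
from .panel import PanelData, at_risk_mask

#: marker used in required-assignment vectors for unconstrained periods
UNCONSTRAINED = -1.0


@dataclass(frozen=True)
class Regime:
    kind: str  # static | delayed_start | dynamic
    label: str
    static_vector: tuple[int, ...] | None = None
    start_day: int | None = None
    covariate: str | None = None
    feed_when_value: int | None = None
    rule: Callable[[int, dict[str, np.ndarray]], np.ndarray] | None = None

    def is_constrained(self, t: int) -> bool:
        """Whether the regime pins down treatment in period ``t``."""
        if self.kind == "delayed_start":
            return t >= self.start_day
        return True

    def required(self, t: int, covariates: dict[str, np.ndarray], n: int) -> np.ndarray:
        """Required treatment at ``t`` given current covariate values.

        Returns an array with entries in {0, 1, UNCONSTRAINED}.  ``covariates``
        maps time-varying covariate names to their period-``t`` values.
        """
        if not self.is_constrained(t):
            return np.full(n, UNCONSTRAINED)
        if self.kind == "static":
            return np.full(n, float(self.static_vector[t]))
        if self.kind == "delayed_start":
            return np.ones(n)
        return np.asarray(self.rule(t, covariates), dtype=float)


def static_regime(vector, label: str | None = None) -> Regime:
    """Regime constraining ``A_t`` to ``vector[t]`` for every period."""
    vec = tuple(int(v) for v in vector)
    if any(v not in (0, 1) for v in vec):
        raise ConfigError("static regime vector must be binary")
    if label is None:
        label = "static_" + "".join(str(v) for v in vec)
    return Regime(kind="static", label=label, static_vector=vec)


def delayed_start_regime(start_day: int, T_plus_1: int = 7, label: str | None = None) -> Regime:
    """Treatment unconstrained before ``start_day``, required 1 from it on."""
    if not 0 <= start_day <= T_plus_1 - 1:
        raise ConfigError(f"start_day={start_day} out of range 0..{T_plus_1 - 1}")
    if label is None:
        label = f"treat_by_day_{start_day + 1}"
    return Regime(kind="delayed_start", label=label, start_day=start_day)


def dynamic_rule_regime(
    covariate_name: str, feed_when_value: int, label: str | None = None
) -> Regime:
    """Treat in period ``t`` iff the named binary covariate equals the trigger value."""
    if feed_when_value not in (0, 1):
        raise ConfigError("feed_when_value must be 0 or 1")
    if label is None:
        label = f"treat_when_{covariate_name}_{feed_when_value}"

    def rule(t: int, cov: dict[str, np.ndarray]) -> np.ndarray:
        if covariate_name not in cov:
            raise ConfigError(f"unknown time-varying covariate: {covariate_name}")
        vals = np.asarray(cov[covariate_name], dtype=float)
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ConfigError(f"dynamic rule covariate {covariate_name} is not binary")
        return (vals == feed_when_value).astype(float)

    return Regime(
        kind="dynamic",
        label=label,
        covariate=covariate_name,
        feed_when_value=feed_when_value,
        rule=rule,
    )


@dataclass
class CounterfactualAssignment:
    """Required treatment at one period, per subject."""

    required: np.ndarray  # 0 / 1 / UNCONSTRAINED
    unconstrained: np.ndarray  # bool
    post_event: np.ndarray  # bool: subject discharged or dead before node A_t


def counterfactual_assignment(
    regime: Regime, panel: PanelData, t: int
) -> CounterfactualAssignment:
    """Vector of treatments the regime requires at period ``t``.

    Subjects already past discharge or death receive their observed
    (carried-forward) value and are flagged ``post_event``.
    """
    if not 0 <= t <= panel.T:
        raise ValueError(f"t={t} out of range 0..{panel.T}")
    cov = {c: panel.z(t, c) for c in (panel.tv_cols if t >= 1 else panel.baseline_cols)}
    req = regime.required(t, cov, panel.n)
    post = at_risk_mask(panel, t) == 0
    req = req.copy()
    req[post] = panel.a(t)[post]
    return CounterfactualAssignment(
        required=req,
        unconstrained=np.full(panel.n, not regime.is_constrained(t)),
        post_event=post,
    )


def follow_indicator(panel: PanelData, regime: Regime, t: int) -> np.ndarray:
    """1 iff the subject's observed treatments match the regime through ``t``.

    Matching is only demanded at constrained periods reached while at risk;
    person-periods after discharge or death count as following (the regime
    only assigns treatment up to the absorbing event).  ``t = -1`` returns
    all ones (nothing is constrained yet).
    """
    follow = np.ones(panel.n, dtype=bool)
    for s in range(0, t + 1):
        ca = counterfactual_assignment(regime, panel, s)
        exempt = ca.unconstrained | ca.post_event
        follow &= exempt | (panel.a(s) == ca.required)
    return follow.astype(float)


def follower_counts(panel: PanelData, regimes: list[Regime]) -> "pd.DataFrame":
    """Cumulative follower counts per regime per day.

    Row ``day k`` counts subjects whose observed treatments are consistent
    with the regime through period ``k-1`` (i.e. through the end of day k).
    """
    import pandas as pd

    rows = {}
    for reg in regimes:
        rows[reg.label] = [
            int(follow_indicator(panel, reg, t).sum()) for t in range(panel.T_plus_1)
        ]
    out = pd.DataFrame(rows, index=pd.Index(range(1, panel.T_plus_1 + 1), name="day"))
    return out
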