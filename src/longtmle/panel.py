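"""Wide-format longitudinal panel with absorbing discharge and death states.

The observed data for one subject are, in causal order,

    O = (Z0, A0, Y1, M1, Z1, A1, ..., A_T, Y_{T+1})

with ``T+1`` daily periods (7 by default).  ``Z0`` collects the baseline
covariates together with the first measurement of the time-varying ones,
``A_t`` is the binary treatment decided during period ``t`` (here: whether the
child was fed at least the caloric threshold on day ``t+1``), ``Y_t`` indicates
live discharge from the unit by the end of period ``t`` and ``M_t`` indicates
death by the end of period ``t``.  Death is a competing absorbing event: once
``M_t = 1`` every later ``Y`` stays 0, and vice versa.  After the first event
all later treatment and covariate cells are deterministically equal to their
last observed (pre-event) values.

Column convention for the wide CSV / DataFrame:

    ``Z0_<name>``  baseline covariates (0-indexed period 0)
    ``A<t>``       treatments, t = 0..T
    ``Y<t>``       discharge indicators, t = 1..T+1
    ``M<t>``       death indicators, t = 1..T  (there is no M_{T+1} node)
    ``Z<t>_<name>`` time-varying covariates, t = 1..T
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import PanelSchemaError, PanelValidationError

#: default covariate schema emulating the cardiac-surgery PICU cohort
DEFAULT_BASELINE = (
    "age_months",
    "sex",
    "weight_kg",
    "height_cm",
    "rachs",
    "arm",
    "vent",
    "renal",
    "infection",
    "inotrope",
)
#: the subset of covariates that is re-measured every day
DEFAULT_TIMEVARYING = ("vent", "renal", "infection", "inotrope")


@dataclass
class PanelData:
    """A validated wide longitudinal table, one row per subject."""

    frame: pd.DataFrame
    T_plus_1: int = 7
    baseline_cols: tuple[str, ...] = DEFAULT_BASELINE
    tv_cols: tuple[str, ...] = DEFAULT_TIMEVARYING

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def T(self) -> int:
        return self.T_plus_1 - 1

    # -- column accessors -------------------------------------------------
    def a(self, t: int) -> np.ndarray:
        return self.frame[f"A{t}"].to_numpy(dtype=float)

    def y(self, t: int) -> np.ndarray:
        if t == 0:
            return np.zeros(self.n)
        return self.frame[f"Y{t}"].to_numpy(dtype=float)

    def m(self, t: int) -> np.ndarray:
        if t == 0:
            return np.zeros(self.n)
        return self.frame[f"M{t}"].to_numpy(dtype=float)

    def z_cols(self, t: int) -> list[str]:
        """Names of the covariate columns measured in period ``t``."""
        if t == 0:
            return [f"Z0_{c}" for c in self.baseline_cols]
        return [f"Z{t}_{c}" for c in self.tv_cols]

    def z(self, t: int, name: str) -> np.ndarray:
        col = f"Z0_{name}" if t == 0 else f"Z{t}_{name}"
        return self.frame[col].to_numpy(dtype=float)

    def expected_columns(self) -> list[str]:
        """All schema columns in causal order."""
        cols = [f"Z0_{c}" for c in self.baseline_cols]
        for t in range(self.T_plus_1):
            cols.append(f"A{t}")
            cols.append(f"Y{t + 1}")
            if t + 1 <= self.T:
                cols.append(f"M{t + 1}")
                cols.extend(f"Z{t + 1}_{c}" for c in self.tv_cols)
        return cols

    def copy(self) -> "PanelData":
        return replace(self, frame=self.frame.copy())

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        baseline: pd.DataFrame,
        A: np.ndarray,
        Y: np.ndarray,
        M: np.ndarray | None = None,
        timevarying: dict[str, np.ndarray] | None = None,
    ) -> "PanelData":
        """Assemble a panel from per-node arrays.

        ``A`` and ``Y`` are (n, T+1); ``M`` is (n, T) (or None when T = 0);
        ``timevarying`` maps a covariate name to its (n, T) array of values
        for periods 1..T.
        """
        A = np.asarray(A)
        Y = np.asarray(Y)
        n, T_plus_1 = A.shape
        T = T_plus_1 - 1
        tv = timevarying or {}
        data: dict[str, np.ndarray] = {}
        for c in baseline.columns:
            data[f"Z0_{c}"] = baseline[c].to_numpy()
        for t in range(T_plus_1):
            data[f"A{t}"] = A[:, t]
            data[f"Y{t + 1}"] = Y[:, t]
            if t + 1 <= T:
                data[f"M{t + 1}"] = np.asarray(M)[:, t]
                for c in tv:
                    data[f"Z{t + 1}_{c}"] = np.asarray(tv[c])[:, t]
        panel = cls(
            frame=pd.DataFrame(data).astype(float),
            T_plus_1=T_plus_1,
            baseline_cols=tuple(baseline.columns),
            tv_cols=tuple(tv.keys()),
        )
        return panel


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`."""

    passed: bool
    violations: list[tuple[int, str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "violations": [
                {"subject": int(s), "rule": r, "period": int(t)}
                for s, r, t in self.violations
            ],
        }

    def to_text(self) -> str:
        if self.passed:
            return "panel OK: no violations"
        lines = [f"panel FAILED: {len(self.violations)} violation(s)"]
        lines += [f"  subject {s}: {r} at t={t}" for s, r, t in self.violations]
        return "\n".join(lines)


def _check_schema(panel: PanelData) -> None:
    missing = [c for c in panel.expected_columns() if c not in panel.frame.columns]
    if missing:
        raise PanelSchemaError(f"missing column(s): {', '.join(missing)}")
    binary_cols = [f"A{t}" for t in range(panel.T_plus_1)]
    binary_cols += [f"Y{t}" for t in range(1, panel.T_plus_1 + 1)]
    binary_cols += [f"M{t}" for t in range(1, panel.T_plus_1)]
    for c in binary_cols:
        vals = panel.frame[c].dropna().unique()
        if not np.isin(vals, [0, 1]).all():
            raise PanelSchemaError(f"column {c} must be binary 0/1")


def first_event_period(panel: PanelData) -> tuple[np.ndarray, np.ndarray]:
    """Per subject: period of the first absorbing event and its type.

    Returns ``(event_t, died)`` where ``event_t[i]`` is the first period with
    ``Y = 1`` or ``M = 1`` (``T+2`` when no event occurs within follow-up) and
    ``died[i]`` flags a death event.
    """
    n, sentinel = panel.n, panel.T_plus_1 + 1
    event_t = np.full(n, sentinel)
    died = np.zeros(n, dtype=bool)
    for t in range(1, panel.T_plus_1 + 1):
        y = panel.y(t) == 1
        m = panel.m(t) == 1 if t <= panel.T else np.zeros(n, dtype=bool)
        new = (y | m) & (event_t == sentinel)
        event_t[new] = t
        died[new & m] = True
    return event_t, died


def validate_panel(panel: PanelData) -> ValidationReport:
    """Check the absorbing-state invariants; never mutates the input.

    Raises :class:`PanelSchemaError` on a malformed schema; invariant
    violations are collected into the returned report.
    """
    _check_schema(panel)
    f = panel.frame
    viol: list[tuple[int, str, int]] = []

    nan_mask = f[panel.expected_columns()].isna()
    if nan_mask.to_numpy().any():
        for i in np.where(nan_mask.any(axis=1))[0]:
            viol.append((int(i), "missing_value", -1))

    Y = np.stack([panel.y(t) for t in range(1, panel.T_plus_1 + 1)], axis=1)
    M = (
        np.stack([panel.m(t) for t in range(1, panel.T_plus_1)], axis=1)
        if panel.T >= 1
        else np.zeros((panel.n, 0))
    )
    for i, t in zip(*np.where(np.diff(Y, axis=1) < 0)):
        viol.append((int(i), "nonmonotone_Y", int(t + 2)))
    if M.shape[1] > 1:
        for i, t in zip(*np.where(np.diff(M, axis=1) < 0)):
            viol.append((int(i), "nonmonotone_M", int(t + 2)))
    both = (Y.max(axis=1) == 1) & (M.max(axis=1) == 1) if M.size else np.zeros(panel.n, bool)
    for i in np.where(both)[0]:
        viol.append((int(i), "death_blocks_discharge", int(np.argmax(M[i]) + 1)))

    # carry-forward after the first event: A_t and Z_t frozen at period e-1
    event_t, died = first_event_period(panel)
    for t in range(panel.T_plus_1):
        post = event_t <= t  # the event happened before node A_t / Z_t
        if not post.any():
            continue
        prev_a = np.select(
            [event_t == e for e in range(1, t + 1)],
            [panel.a(e - 1) for e in range(1, t + 1)],
        )
        bad = post & (panel.a(t) != prev_a)
        for i in np.where(bad)[0]:
            viol.append((int(i), "carry_forward_A", t))
        if 1 <= t <= panel.T:
            for c in panel.tv_cols:
                prev_z = np.select(
                    [event_t == e for e in range(1, t + 1)],
                    [panel.z(e - 1, c) for e in range(1, t + 1)],
                )
                badz = post & (panel.z(t, c) != prev_z)
                for i in np.where(badz)[0]:
                    viol.append((int(i), "carry_forward_Z", t))

    viol = sorted(set(viol))
    return ValidationReport(passed=not viol, violations=viol)


def apply_absorbing_states(panel: PanelData) -> PanelData:
    """Overwrite all post-event cells with carried-forward values.

    Idempotent; the pre-event segments are untouched.  A subject whose first
    event is at period ``e`` keeps ``A_{e-1}`` and ``Z_{e-1}`` for every later
    treatment/covariate node, ``Y`` stays at 1 after a discharge, and ``M``
    stays at 1 (with ``Y`` forced to 0) after a death.
    """
    out = panel.copy()
    f = out.frame
    event_t, died = first_event_period(panel)
    for t in range(1, panel.T_plus_1 + 1):
        post = event_t <= t
        y_t = panel.y(t).copy()
        y_t[post & ~died] = 1.0
        y_t[post & died] = 0.0
        f[f"Y{t}"] = y_t
        if t <= panel.T:
            m_t = panel.m(t).copy()
            m_t[post & died] = 1.0
            m_t[post & ~died] = 0.0
            f[f"M{t}"] = m_t
    for t in range(panel.T_plus_1):
        post = event_t <= t
        if not post.any():
            continue
        sel = [event_t == e for e in range(1, t + 1)]
        a_t = panel.a(t).copy()
        a_t[post] = np.select(sel, [panel.a(e - 1) for e in range(1, t + 1)])[post]
        f[f"A{t}"] = a_t
        if 1 <= t <= panel.T:
            for c in panel.tv_cols:
                z_t = panel.z(t, c).copy()
                z_t[post] = np.select(sel, [panel.z(e - 1, c) for e in range(1, t + 1)])[post]
                f[f"Z{t}_{c}"] = z_t
    return out


def at_risk_mask(panel: PanelData, t: int) -> np.ndarray:
    """1 for subjects still in the unit and alive through period ``t``.

    ``at_risk_mask(panel, 0)`` is all ones (no event node precedes A_0).
    """
    if not 0 <= t <= panel.T:
        raise ValueError(f"t={t} out of range 0..{panel.T}")
    alive = np.ones(panel.n, dtype=bool)
    for s in range(1, t + 1):
        alive &= (panel.y(s) == 0) & (panel.m(s) == 0)
    return alive.astype(float)


def history_matrix(
    panel: PanelData,
    t: int,
    markov_order: int | str = 2,
    include_treatment_at_t: bool = False,
) -> pd.DataFrame:
    """Design table of covariate/treatment history for period-``t`` models.

    Contains every baseline column plus the ``Z`` and ``A`` columns from the
    ``min(markov_order, t+1)`` most recent periods up to and including period
    ``t``'s covariates.  Treatments strictly before ``t`` are included;
    ``A_t`` itself only when ``include_treatment_at_t`` is set (used by the
    sequential outcome regressions, which condition on the treatment of the
    same period).
    """
    if not 0 <= t <= panel.T:
        raise ValueError(f"t={t} out of range 0..{panel.T}")
    if markov_order == "full":
        k = t + 1
    else:
        if not (isinstance(markov_order, (int, np.integer)) and markov_order >= 1):
            raise ValueError("markov_order must be a positive integer or 'full'")
        k = min(int(markov_order), t + 1)
    cols = [f"Z0_{c}" for c in panel.baseline_cols]
    for s in range(t - k + 1, t + 1):
        if s >= 1:
            cols.extend(f"Z{s}_{c}" for c in panel.tv_cols)
        if s < t:
            cols.append(f"A{s}")
    if include_treatment_at_t:
        cols.append(f"A{t}")
    return panel.frame[cols].astype(float)


# -- CSV interface --------------------------------------------------------

_COL_RE = re.compile(r"^(Z(\d+)_(\w+)|A(\d+)|Y(\d+)|M(\d+))$")


def read_panel_csv(path, validate: bool = True) -> PanelData:
    """Read a wide panel CSV, infer the schema from the header, validate.

    Absorbing states are applied (a no-op on already-consistent files) and a
    :class:`PanelValidationError` carrying the full report is raised when the
    pre-event segments violate the invariants.
    """
    frame = pd.read_csv(path)
    baseline, tv, t_max_y = [], [], 0
    for col in frame.columns:
        m = _COL_RE.match(col)
        if m is None:
            raise PanelSchemaError(f"unrecognized column name: {col}")
        if m.group(2) is not None:
            t, name = int(m.group(2)), m.group(3)
            if t == 0:
                baseline.append(name)
            elif t == 1 and name not in tv:
                tv.append(name)
        elif m.group(5) is not None:
            t_max_y = max(t_max_y, int(m.group(5)))
    if t_max_y == 0:
        raise PanelSchemaError("no outcome column Y<t> found")
    panel = PanelData(
        frame=frame,
        T_plus_1=t_max_y,
        baseline_cols=tuple(baseline),
        tv_cols=tuple(tv),
    )
    _check_schema(panel)
    if validate:
        report = validate_panel(panel)
        if not report.passed:
            raise PanelValidationError(report)
    return apply_absorbing_states(panel)


def write_panel_csv(panel: PanelData, path) -> None:
    panel.frame[panel.expected_columns()].to_csv(path, index=False)
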