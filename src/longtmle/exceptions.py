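"""Exception hierarchy for longtmle."""


class LongTMLEError(Exception):
    """Base class for all package errors."""


class PanelSchemaError(LongTMLEError):
    """The wide table is missing a column or has a malformed one."""


class PanelValidationError(LongTMLEError):
    """A panel violated the absorbing-state / monotonicity invariants."""

    def __init__(self, report):
        self.report = report
        lines = ", ".join(
            f"(subject {s}, {rule}, t={t})" for s, rule, t in report.violations[:5]
        )
        more = "" if len(report.violations) <= 5 else f" and {len(report.violations) - 5} more"
        super().__init__(f"panel validation failed: {lines}{more}")


class PositivityError(LongTMLEError):
    """No at-risk regime followers remain, or a follower has zero support."""


class EstimationError(LongTMLEError):
    """An estimator could not be computed (e.g. empty fitting set)."""


class ConfigError(LongTMLEError):
    """A run configuration is malformed."""
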