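"""Exception hierarchy shared across the package."""


class MobilearnError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(MobilearnError, ValueError):
    """A generator or run specification is internally inconsistent."""


class InsufficientDataError(MobilearnError, ValueError):
    """A series is too short (or a block empty) for the requested operation."""


class DegenerateBaselineError(MobilearnError, ValueError):
    """The baseline-phase mean displacement rate is zero, so the baseline
    ratio is undefined.  Usually signals a motionless synthetic limb."""


class IntegrationFailureError(MobilearnError, RuntimeError):
    """The ODE integration produced non-finite state."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class IncompleteDesignError(MobilearnError, ValueError):
    """An ANOVA table is missing cells required by the design."""


class DegenerateVarianceError(MobilearnError, ValueError):
    """An error term has zero variance; F statistics are undefined."""


class FittingFailureError(MobilearnError, RuntimeError):
    """Every candidate in a parameter grid failed to produce a usable fit."""


class SessionParseError(MobilearnError, ValueError):
    """A session CSV does not conform to the documented dialect."""
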