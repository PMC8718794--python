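"""Exception hierarchy shared across the package."""


class AlternansError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AlternansError, ValueError):
    """A generator or model parameter violates its precondition."""


class FitFailureError(AlternansError, RuntimeError):
    """Nonlinear fit failed to converge after multistart.

    Carries per-replicate diagnostics in ``details`` when available.
    """

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}


class IntegrationFailureError(AlternansError, RuntimeError):
    """A simulation state variable became non-finite."""

    def __init__(self, message, field=None, time_ms=None):
        super().__init__(message)
        self.field = field
        self.time_ms = time_ms


class NormalizationError(AlternansError, ValueError):
    """Trace or count normalization is impossible (e.g. zero baseline)."""


class InsufficientDataError(AlternansError, ValueError):
    """Too few observations for the requested statistic."""


class InvalidMetricError(AlternansError, ValueError):
    """Metric inputs violate their ordering/positivity constraints."""
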