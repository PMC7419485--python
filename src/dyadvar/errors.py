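"""Exception hierarchy for dyadvar."""


class DyadvarError(Exception):
    """Base class for all package errors."""


class SchemaError(DyadvarError):
    """An input file is missing required columns or is malformed."""


class ValidationError(DyadvarError):
    """A record violates a domain invariant (vocabulary, sign, window)."""


class GapError(DyadvarError):
    """A dyad is missing an entire month, so equal spacing cannot hold."""


class ConsistencyError(DyadvarError):
    """Contradictory metadata, e.g. one dyad labelled with two groups."""


class DegenerateSeriesError(DyadvarError):
    """A series has zero variance, so correlations are undefined."""


class EstimationError(DyadvarError):
    """Least-squares estimation failed (rank deficiency, too few rows)."""


class StabilityError(DyadvarError):
    """The fitted VAR is not stationary; forward projection would diverge."""


class ConvergenceError(DyadvarError):
    """No lag order within the allowed range produced admissible residuals.

    Carries the full per-lag diagnostics audit trail in ``audit``.
    """

    def __init__(self, message, audit=None):
        super().__init__(message)
        self.audit = audit or []


class BootstrapError(DyadvarError):
    """Too many bootstrap replicates failed to re-estimate."""


class ConfigurationError(DyadvarError):
    """A run or generator configuration violates its invariants."""
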