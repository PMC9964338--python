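"""Exception hierarchy for the neosps package."""


class NeospsError(Exception):
    """Base class for all package errors."""


class ValidationError(NeospsError, ValueError):
    """An input violates a documented precondition; the message names the field."""


class InconsistencyError(NeospsError, ValueError):
    """Jointly supplied inputs contradict each other (e.g. a negative implied
    confusion-matrix cell when combining a score distribution with band counts)."""


class SchemaError(NeospsError, ValueError):
    """A tabular input does not conform to the cohort CSV dialect."""


class UnsupportedConfigurationError(NeospsError):
    """A configuration is valid but outside the analytic regime of the
    requested operation (e.g. closed-form metrics with correlated indicators)."""
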