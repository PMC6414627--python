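"""Exception hierarchy shared across the package."""


class CrestCurveError(Exception):
    """Base class for all crestcurve errors."""


class ParseError(CrestCurveError):
    """A file could not be parsed; the message names the offending line."""


class ContentError(CrestCurveError):
    """A file parsed but its content violates a requirement (e.g. too few points)."""


class SchemaError(CrestCurveError):
    """A tabular file is missing columns or carries non-numeric coordinates."""


class InvalidParameterError(CrestCurveError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(CrestCurveError):
    """Geometrically degenerate input (zero length, too few points, ...)."""


class InsufficientSampleError(CrestCurveError):
    """Too few specimens or groups for the requested statistic."""


class ContractError(CrestCurveError):
    """An internal precondition on shapes (centering, unit size, matching k) failed."""
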