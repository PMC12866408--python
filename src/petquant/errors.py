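"""Exception hierarchy shared across the package.

All petquant errors derive from :class:`PetquantError` so callers can catch
everything the library raises with a single ``except``; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class PetquantError(Exception):
    """Base class for all errors raised by petquant."""


class ValidationError(PetquantError, ValueError):
    """Input data violate a documented invariant (negative activity, bad
    fraction, non-contiguous frames, ...)."""


class SchemaError(ValidationError):
    """A file on disk does not conform to the tab-separated schema."""


class UnderDeterminedError(ValidationError):
    """Too few data points to identify the requested model."""


class CoverageError(ValidationError):
    """The frame schedule extends beyond the span of the input function."""


class InvalidModelError(ValidationError):
    """A fitted/supplied model predicts impossible values (negative ratio,
    fraction outside [0, 1]) over the required time span."""


class DegenerateInputError(ValidationError):
    """Input carries no usable signal (e.g. an all-zero time-activity curve)."""


class FitFailureError(PetquantError, RuntimeError):
    """A nonlinear fit failed to converge on all restarts."""


class UndefinedMetricError(ValidationError):
    """A metric is undefined for the given values (e.g. zero pair mean)."""
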