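"""Exception hierarchy for protods.

All errors raised by the library derive from :class:`ProtoDSError` so callers
can catch package failures with a single except clause.
"""


class ProtoDSError(Exception):
    """Base class for all protods errors."""


class InputError(ProtoDSError, ValueError):
    """Malformed or inconsistent user input (shape mismatch, bad labels...)."""


class ConfigurationError(ProtoDSError, ValueError):
    """A configuration that cannot be satisfied (empty band window, ...)."""


class CalibrationReferenceError(ProtoDSError, ValueError):
    """White minus dark reference is non-positive where division occurs."""


class DegenerateInstanceError(ProtoDSError, ValueError):
    """An instance ended up with zero effective pixels."""


class FormatError(ProtoDSError, ValueError):
    """An on-disk cube or manifest could not be parsed."""


class SupportError(ProtoDSError, ValueError):
    """A class has no support samples when prototypes are required."""


class DatasetError(ProtoDSError, ValueError):
    """The dataset violates a structural precondition (too few instances...)."""


class UndefinedMetricError(ProtoDSError, ValueError):
    """A metric is undefined for the given labels (empty class, no negatives)."""


class TrainingError(ProtoDSError, RuntimeError):
    """Optimization produced non-finite values."""


class NumericError(ProtoDSError, ValueError):
    """Non-finite values where finite numbers are required."""
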