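"""Exception hierarchy used at module boundaries.

Every documented failure mode maps onto one of these classes so callers can
distinguish malformed files (FormatError), bad data values (DataError),
invalid trial records (ValidationError), bad configuration (ConfigurationError),
and statistical procedures invoked on inadequate input (InferenceError).
"""


class VRHeadMotionError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VRHeadMotionError):
    """A file does not match the declared dialect (e.g. a named column is missing)."""


class DataError(VRHeadMotionError):
    """Well-formed file, bad content: non-numeric cells, non-monotonic time, bad grids."""


class GridError(DataError):
    """An operation that requires a uniform shared time grid was given something else."""


class ValidationError(VRHeadMotionError):
    """A trial record violates a range or consistency invariant."""


class ConfigurationError(VRHeadMotionError):
    """Inconsistent or incomplete configuration, detected before any computation."""


class InferenceError(VRHeadMotionError):
    """A statistical summary was requested on input that cannot support it."""
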