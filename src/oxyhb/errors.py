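"""Exception hierarchy for oxyhb.

All validation and domain failures derive from :class:`OxyhbError` so callers
can distinguish pipeline problems from programming errors.
"""


class OxyhbError(Exception):
    """Base class for all oxyhb errors."""


class FormatError(OxyhbError):
    """A table or config file does not have the expected structure."""


class ValidationError(OxyhbError):
    """A value violates a physical or protocol invariant."""


class FitError(OxyhbError):
    """A regression or curve fit is degenerate or non-physical."""


class GroupingError(OxyhbError):
    """Inputs that must share a condition or temperature do not."""


class CalibrationError(OxyhbError):
    """The simulator could not be calibrated to the requested targets."""
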