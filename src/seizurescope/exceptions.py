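"""Exception hierarchy.

All package errors derive from :class:`SeizurescopeError` so callers can catch
one base class; each also subclasses ``ValueError`` for drop-in compatibility
with code that validates arguments the numpy/scipy way.
"""


class SeizurescopeError(ValueError):
    """Base class for all errors raised by seizurescope."""


class ParameterError(SeizurescopeError):
    """A configuration or function parameter is invalid."""


class InputError(SeizurescopeError):
    """Input data violates a structural precondition (shape, kind, range)."""


class NumericalError(SeizurescopeError):
    """A computation is numerically undefined for the given data."""


class EditError(SeizurescopeError):
    """A manual event-train correction references a non-existent event."""
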