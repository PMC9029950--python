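"""Exception hierarchy shared across the pipeline."""


class LeukoflowError(Exception):
    """Base class for all package errors."""


class FcsFormatError(LeukoflowError, ValueError):
    """Raised when a listmode file is unreadable or violates the FCS standard."""


class ConfigurationError(LeukoflowError, ValueError):
    """Raised for invalid user configuration (unknown method, bad panel, ...)."""


class InsufficientDataError(LeukoflowError, ValueError):
    """Raised when an operation has too few (or degenerate) events to proceed."""
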