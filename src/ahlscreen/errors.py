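"""Exception types shared across the package."""


class AhlScreenError(Exception):
    """Base class for all package errors."""


class InvalidTargetError(AhlScreenError):
    """Raised for chemically impossible AHL target definitions."""


class UnsupportedDataError(AhlScreenError):
    """Raised when an input file holds data the pipeline cannot process
    (e.g. profile-mode spectra where centroids are required)."""


class ValidationError(AhlScreenError):
    """Raised when an in-memory object violates its invariants."""
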