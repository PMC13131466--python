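"""Exception types shared across the package."""


class AneucloneError(Exception):
    """Base class for all package errors."""


class FormatError(AneucloneError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(AneucloneError):
    """Parsed data violate an invariant of the in-memory model."""


class AnalysisError(AneucloneError):
    """An analysis was asked to run on inputs it cannot handle."""
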