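"""Exception hierarchy shared across the package."""


class TempotagError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TempotagError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(TempotagError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class FormatError(TempotagError, IOError):
    """A file could not be parsed in the expected on-disk format."""
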