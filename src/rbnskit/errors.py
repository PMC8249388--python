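"""Exception types shared across the package."""


class RbnskitError(Exception):
    """Base class for all package-specific errors."""


class PatternSyntaxError(RbnskitError, ValueError):
    """Raised when an IUPAC/bounded-gap motif string cannot be parsed.

    Carries ``position``, the 0-based offset of the offending token in the
    raw pattern string (or ``None`` when the error is not positional).
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class FastqParseError(RbnskitError, ValueError):
    """Raised for truncated or malformed FASTQ records; names the record index."""


class InvalidInputError(RbnskitError, ValueError):
    """Raised when numeric inputs make an operation undefined (e.g. zero denominators)."""


class InfeasibleSpecError(RbnskitError, ValueError):
    """Raised when a simulation spec cannot be satisfied (e.g. motif longer than region)."""
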