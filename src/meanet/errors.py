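"""Exception types shared across the package."""


class MeanetError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MeanetError, ValueError):
    """A parameter violates a documented precondition."""


class NoDataError(MeanetError):
    """An operation that requires data received an empty input."""


class DegenerateInputError(MeanetError):
    """Input is formally valid but the statistic is undefined on it."""


class FormatError(MeanetError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PlacementError(MeanetError):
    """Requested burst windows cannot be placed without overlap."""


class NoPathError(MeanetError):
    """A graph has no finite shortest path between any pair of nodes."""
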