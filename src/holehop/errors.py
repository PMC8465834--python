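"""Typed exceptions raised by holehop.

All package errors derive from :class:`HoleHopError` so callers (and the CLI)
can catch everything the library raises with one except clause.
"""


class HoleHopError(Exception):
    """Base class for all holehop errors."""


class InvalidParameterError(HoleHopError, ValueError):
    """A physical parameter violates its domain (e.g. negative rate, T <= 0)."""


class ConvergenceError(HoleHopError, RuntimeError):
    """An iterative solver failed to reach its stopping criterion.

    Carries the residual transient mass reached, when applicable.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class StructuralError(HoleHopError, ValueError):
    """A kinetic scheme is structurally unsolvable (singular transient block)."""


class UnattainableTargetError(HoleHopError, ValueError):
    """A calibration target lies outside the attainable response range.

    ``supremum`` holds the largest (or smallest) attainable value found.
    """

    def __init__(self, message: str, supremum: float | None = None):
        super().__init__(message)
        self.supremum = supremum


class DegenerateInputError(HoleHopError, ValueError):
    """An input series is degenerate for the requested statistic (e.g. zero variance)."""


class MissingChannelError(HoleHopError, ValueError):
    """A trace lacks a channel required by the operation."""


class AlignmentError(HoleHopError, ValueError):
    """Replicate traces do not share an identical time grid."""


class SingularityError(HoleHopError, ValueError):
    """A source charge (nearly) coincides with the potential probe point."""


class ParseError(HoleHopError, ValueError):
    """A text input file failed validation; ``line`` is 1-based when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConfigError(HoleHopError, ValueError):
    """A configuration mapping is invalid (unknown keys, bad values)."""
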