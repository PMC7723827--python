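"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`LostnessError`, so callers can catch one base class at a CLI or
pipeline boundary.
"""

from __future__ import annotations


class LostnessError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(LostnessError):
    """An input file does not conform to the documented schema."""


class UnknownIdentifierError(LostnessError, KeyError):
    """A node, task, or objective id does not resolve."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return LostnessError.__str__(self)


class UnreachableError(LostnessError):
    """No path exists between two nodes that must be connected."""


class ParseError(LostnessError):
    """An event log file is malformed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(LostnessError):
    """An event stream violates task/objective structure (e.g. a task
    completes without ever starting, or an objective completes twice)."""


class DegenerateSegmentError(LostnessError):
    """The lostness formula is undefined for a segment with no movement
    (S = 0 or N = 0); callers should apply the skip rule: degenerate
    segments contribute zero counts to summed measures and are flagged,
    never scored, individually."""


class InconsistentCountsError(LostnessError):
    """(R, S, N) violate R <= N <= S and cannot come from a real path."""


class ConfigurationError(LostnessError):
    """A simulation or run configuration is infeasible."""


class SingularityError(LostnessError):
    """Design matrix is exactly collinear; names the dependent columns."""

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        self.columns = columns
        super().__init__(message)


class InsufficientDataError(LostnessError):
    """Too few rows/values for the requested statistic."""


class DegenerateDataError(LostnessError):
    """A statistic is undefined on this input (e.g. a constant vector)."""


class PairingError(LostnessError):
    """Paired samples have mismatched lengths."""
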