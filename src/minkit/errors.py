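"""Exception hierarchy shared across the package.

Every error raised by the public API derives from :class:`MinkitError`, so
callers (and the CLI) can distinguish domain errors from genuine bugs or
I/O failures.
"""

from __future__ import annotations


class MinkitError(Exception):
    """Base class for all domain errors raised by this package."""


class InvalidInputError(MinkitError):
    """Input data violates a structural rule (mixed weights, bad range...)."""


class ParseError(InvalidInputError):
    """One or more rows of a text source could not be parsed.

    Carries the offending line numbers so the caller can report them.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class InvalidParameterError(MinkitError):
    """A query parameter is outside its documented domain."""


class UnknownInteractorError(MinkitError):
    """A referenced interactor id is not a vertex of the graph."""

    def __init__(self, interactor_id: str):
        super().__init__(f"unknown interactor: {interactor_id!r}")
        self.interactor_id = interactor_id


class WrongModeError(MinkitError):
    """A weighted operation was applied to an unweighted graph (or vice versa)."""


class UndefinedStatisticError(MinkitError):
    """The requested statistic is undefined for this graph (e.g. density on |V| < 2)."""


class ContractViolationError(MinkitError):
    """A user-supplied superstep function breaks its algebraic contract."""
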