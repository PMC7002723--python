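"""Typed exceptions raised across the package."""

from __future__ import annotations


class TacnaError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TacnaError):
    """A file could not be parsed.

    Carries the offending path and, when known, the 1-based line number.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f", line {line}"
            loc += "]"
        super().__init__(message + loc)


class ValidationError(TacnaError):
    """An in-memory object violates one of its invariants."""


class NoConsensusError(TacnaError):
    """Credibility filtering removed every component cluster."""


class NothingToReconstructError(TacnaError):
    """No component was called as copy-number driven; masking is undefined."""


class IcaConvergenceWarning(UserWarning):
    """An ICA run hit the iteration cap without converging (after one retry)."""
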