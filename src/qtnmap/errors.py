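"""Exception hierarchy.

Grouped so the CLI can map error families to distinct exit codes:
I/O problems, validation/domain problems, and numerical problems.
"""


class QtnmapError(Exception):
    """Base class for all package errors."""


class ParseError(QtnmapError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(QtnmapError):
    """Structurally well-formed input that violates a model invariant."""


class DomainError(QtnmapError):
    """Argument outside the mathematical domain of an operation."""


class LookupMissError(QtnmapError, KeyError):
    """Requested ID not present in the container."""


class SingularityError(QtnmapError):
    """Design matrix rank-deficient (perfectly collinear predictors)."""


class FeasibilityError(QtnmapError):
    """Simulation constraints could not be satisfied within the retry budget."""
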