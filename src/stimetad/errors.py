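"""Exception hierarchy.

All package-specific failures derive from :class:`StimetadError` so callers
can catch one base class at pipeline boundaries.
"""


class StimetadError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(StimetadError):
    """A time-ordered record (e.g. hill deposition times) was fed out of order."""


class NotReachedError(StimetadError):
    """A censored trajectory (target never reached) was used where a
    first-passage event is required."""


class FormatError(StimetadError):
    """A text input file violates its format contract.

    Carries the 1-based line number when the offence is attributable to a
    single line.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientDataError(StimetadError):
    """Fewer samples than the operation's minimum."""


class DegenerateSampleError(StimetadError):
    """All sample values identical; no fit is defined."""


class PathologicalFitError(StimetadError):
    """A fit produced a non-positive rate or otherwise unusable parameters."""


class InferenceFailureError(StimetadError):
    """Every bootstrap batch failed; no summary can be formed."""
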