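"""Exception hierarchy for the audit pipelines.

Every failure a pipeline stage can raise derives from :class:`VauditError`
so the audit orchestrator can attribute an abort to its stage.
"""


class VauditError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VauditError):
    """An input file does not conform to its declared format."""


class UnsupportedGeometryError(FormatError):
    """A dose grid uses a geometry the pipelines do not model (oblique or
    non-uniformly spaced)."""


class OutOfBoundsError(VauditError):
    """A requested coordinate or detector position lies outside a grid."""


class ArgumentError(VauditError):
    """An operation was called with arguments violating its contract."""


class CalibrationError(VauditError):
    """A film calibration fit is unusable (e.g. non-monotone curve)."""


class FiducialDetectionError(VauditError):
    """Registration marks could not be located unambiguously."""


class EmptyAnalysisError(VauditError):
    """No reference point survived the dose threshold; gamma statistics
    would be undefined."""


class ParseError(FormatError):
    """A text input is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(VauditError):
    """Parsed content is well-formed but inconsistent (duplicate or unknown
    detector ids, layout outside image bounds, ...)."""
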