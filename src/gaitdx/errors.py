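"""Exception hierarchy for the gaitdx pipeline.

Every stage raises a subclass of :class:`GaitdxError` so callers can catch
pipeline problems separately from programming errors.
"""


class GaitdxError(Exception):
    """Base class for all gaitdx-specific errors."""


class MarkerSetError(GaitdxError):
    """The 19-marker set is incomplete or malformed."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"marker-set incomplete: missing {', '.join(self.missing)}")


class FixtureParseError(GaitdxError):
    """A plain-text trial fixture could not be parsed."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientStepsError(GaitdxError):
    """Too few gait events to delimit at least one complete step."""


class DegenerateGeometryError(GaitdxError):
    """Coincident markers make a triplet angle undefined."""


class TrialTooShortError(GaitdxError):
    """Trial has fewer frames than one sequence window."""


class CannotSplitError(GaitdxError):
    """A form has too few patients for a patient-wise partition."""
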