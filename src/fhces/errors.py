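"""Exception hierarchy for the fhces package.

All package-specific failures derive from :class:`FHCESError` so callers can
catch one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal faults.
"""


class FHCESError(Exception):
    """Base class for all fhces errors."""


class InvalidParameterError(FHCESError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive dt)."""


class InsufficientDesignError(FHCESError, ValueError):
    """Too few distinct concentrations / traces to support the analysis."""


class DegenerateControlError(FHCESError, ValueError):
    """Control readout is zero or negative; a ratio cannot be formed."""


class AlignmentError(FHCESError, ValueError):
    """Traces are not aligned to a common decay origin or are missing marks."""


class OutOfRangeError(FHCESError, ValueError):
    """A requested readout time lies outside the recorded trace."""


class NoCrossingError(FHCESError, ValueError):
    """The fitted curve never crosses the requested response level."""


class InvalidControlError(FHCESError, ValueError):
    """Control curve carries no usable signal (e.g. flat lysis)."""


class UnreliableFitError(FHCESError, ValueError):
    """A fit did not converge or its EC50 fell outside the trusted range."""


class MissingDataError(FHCESError, ValueError):
    """A required score component is absent in strict mode."""


class InvalidRatioError(FHCESError, ValueError):
    """A score component is negative or non-finite."""


class InvalidScoreError(FHCESError, ValueError):
    """A CES value is non-finite and cannot be classified."""


class InvalidAssayError(FHCESError, ValueError):
    """Unknown assay label."""


class InvalidPanelError(FHCESError, ValueError):
    """Panel definition violates its contract (e.g. no control entry)."""


class ParseError(FHCESError, ValueError):
    """A delimited-text input could not be parsed.

    Carries ``line`` (1-based) when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DuplicateRecordError(FHCESError, ValueError):
    """A registry contains the same variant name twice."""


class NoDataError(FHCESError, ValueError):
    """An operation was asked to summarize an empty results set."""


class PipelineStageError(FHCESError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
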