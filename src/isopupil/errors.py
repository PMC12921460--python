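"""Exception hierarchy for the isopupil pipeline.

All library errors derive from :class:`IsopupilError` so callers can catch
pipeline failures without masking programming errors.
"""


class IsopupilError(Exception):
    """Base class for all isopupil errors."""


class TraceFormatError(IsopupilError):
    """A session file is malformed (missing columns, unparseable values)."""


class EmptyTraceError(IsopupilError):
    """Fewer than two usable samples remain after reading a session."""


class ConfigError(IsopupilError):
    """A configuration value is out of its valid range."""


class PreconditionError(IsopupilError):
    """An operation's input violates a documented precondition."""


class UnrecoverableTraceError(IsopupilError):
    """Every sample of a trace is flagged as artifact; nothing to interpolate from."""


class MissingPhaseError(IsopupilError):
    """The trace does not cover a protocol phase required by a metric."""


class MissingConditionError(IsopupilError):
    """A required load condition (low/high) has no samples."""


class UndefinedRatioError(IsopupilError):
    """Velocity ratio requested with a non-positive component velocity."""


class DegenerateDataError(IsopupilError):
    """A statistical test received degenerate input (zero variance, all ties)."""


class InsufficientDataError(IsopupilError):
    """Fewer usable sessions than a cohort operation requires."""
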