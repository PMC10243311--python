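"""Exception hierarchy for breathing-trace QA.

Every error raised by the package derives from :class:`BreathQAError`, so
callers (and the CLI exit-code mapping) can distinguish analysis failures
from programming errors.
"""


class BreathQAError(Exception):
    """Base class for all package errors."""


class VxpFormatError(BreathQAError):
    """A trace file violates the expected dialect (bad header key, ragged row)."""


class TraceDataError(BreathQAError):
    """Structurally parseable data that violates trace invariants
    (non-monotone timestamps, duplicate ticks, single-sample trace)."""


class EmptyTraceError(BreathQAError):
    """The data section contains no samples."""


class ConfigError(BreathQAError):
    """An analysis or tolerance configuration value is out of range."""


class InsufficientBreathingError(BreathQAError):
    """Too few breathing extrema to analyse the trace."""


class InsufficientMarksError(BreathQAError):
    """Fewer than two vendor P/Z marks present."""


class InsufficientDataError(BreathQAError):
    """A cohort-level statistic was requested on too few records."""


class UndefinedMetricError(BreathQAError):
    """A derived metric has a zero/undefined denominator."""


class TraceSpecError(BreathQAError):
    """A synthetic-trace specification is infeasible or invalid."""
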