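"""Exception hierarchy.

Validation problems raise :class:`ParameterError` (a ``ValueError``), file
problems raise :class:`FormatError` / :class:`DataError`, and analyses that
cannot proceed raise :class:`InsufficientDataError`. The CLI maps any
:class:`BreathComplexError` to exit code 2.
"""


class BreathComplexError(Exception):
    """Base class for all package errors."""


class ParameterError(BreathComplexError, ValueError):
    """A parameter violates its documented domain."""


class ConfigurationError(BreathComplexError):
    """A configuration is internally inconsistent (e.g. overlapping artifact epochs)."""


class FormatError(BreathComplexError):
    """A file does not conform to the expected on-disk format."""


class DataError(BreathComplexError):
    """File parsed but its contents are invalid (NaN/Inf samples, ...)."""


class InsufficientDataError(BreathComplexError):
    """Not enough data for the requested analysis."""


class DegenerateSeriesError(BreathComplexError):
    """The series has zero variance where variance is required."""


class PipelineError(BreathComplexError):
    """Every recording in a cohort failed; carries the per-subject report."""

    def __init__(self, message, failures=None):
        super().__init__(message)
        self.failures = failures or []
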