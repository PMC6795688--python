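"""Exception hierarchy shared across the package.

Three top-level failure classes mirror the CLI exit codes: configuration
problems (bad dialects, missing columns, malformed config files), input
problems (empty or unusable data), and pipeline problems (a stage that
cannot proceed, e.g. an empty instrument set after filtering).
"""


class BodyMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BodyMRError):
    """A dialect, config file or parameter set is malformed."""


class InputError(BodyMRError):
    """Input data are unusable (zero valid rows, zero totals, ...)."""


class PipelineError(BodyMRError):
    """A pipeline stage cannot proceed; carries a stage trace."""

    def __init__(self, message: str, stage_trace: list[str] | None = None):
        super().__init__(message)
        self.stage_trace = list(stage_trace or [])


class InsufficientInstrumentsError(InputError):
    """An estimator or diagnostic needs more instruments than supplied."""


class UndefinedRatioError(InputError):
    """Wald ratio requested for an instrument with zero exposure effect."""
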