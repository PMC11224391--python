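"""Exception hierarchy for stratmr."""


class StratMRError(Exception):
    """Base class for all stratmr errors."""


class ConfigurationError(StratMRError, ValueError):
    """Invalid configuration values (frequencies, correlations, stratum sizes...)."""


class CalibrationError(StratMRError, RuntimeError):
    """A calibration target (noise variance, outcome intercept) cannot be reached."""


class InputError(StratMRError, ValueError):
    """Malformed or degenerate input data."""


class AdjustmentError(StratMRError, ValueError):
    """Seasonal adjustment cannot be performed (e.g. empty reference month)."""


class EstimationError(StratMRError, RuntimeError):
    """A regression model could not be estimated."""


class WeakInstrumentError(EstimationError):
    """The genetic association with the exposure is indistinguishable from zero,
    so a ratio estimate would be numerically unstable and silently misleading."""
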