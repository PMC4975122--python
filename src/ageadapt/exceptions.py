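"""Exception hierarchy shared across the package."""


class AgeAdaptError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AgeAdaptError, ValueError):
    """Invalid configuration (unknown labels, bad parameter values)."""


class InvalidParameterError(ConfigError):
    """Model parameters violate their invariants (e.g. sigma <= 0)."""


class DataValidationError(AgeAdaptError, ValueError):
    """Input data violate the ratings schema; message names the offending row."""


class EmptyDataError(DataValidationError):
    """A stage received an empty dataset."""


class InsufficientDataError(DataValidationError):
    """Too few points for the requested fit or test."""


class DegenerateRegressionError(AgeAdaptError, ValueError):
    """Regression requested on constant x (slope undefined)."""


class DegenerateTestError(AgeAdaptError, ValueError):
    """Signed-rank test on all-zero differences (no information)."""


class FitFailureError(AgeAdaptError, RuntimeError):
    """Every optimizer restart failed to converge."""
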