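"""Exception hierarchy.

``ValidationError`` subclasses indicate malformed inputs or configuration
(CLI exit code 2); other ``PhluxError`` subclasses indicate runtime
failures of an otherwise valid analysis (CLI exit code 3).
"""


class PhluxError(Exception):
    """Base class for all phlux errors."""


class ValidationError(PhluxError):
    """Invalid input data, layout, or configuration."""


class ConfigError(ValidationError):
    """Inconsistent or incomplete run configuration."""


class DataError(ValidationError):
    """Malformed or out-of-spec measurement data."""


class LayoutError(ValidationError):
    """Invalid plate layout (duplicate wells, too many wells, ...)."""


class CalibrationError(ValidationError):
    """Standards unusable for fitting a calibration curve."""


class OperatingRangeError(PhluxError, ValueError):
    """A value fell outside the operational window of a fitted curve."""


class SolverError(PhluxError):
    """The charge-balance root finder could not bracket a solution."""


class SimulationError(PhluxError):
    """Simulated trajectory leaves the configured detection range."""


class FitError(PhluxError):
    """Rate-decay fit impossible on the given bins."""


class InsufficientSignalError(FitError):
    """Too little uncensored production to form even a single bin."""
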