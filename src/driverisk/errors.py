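"""Exception hierarchy shared across the package."""


class DriveriskError(Exception):
    """Base class for all package errors."""


class SchemaError(DriveriskError):
    """An input table is missing required columns or has a bad dialect."""


class DataError(DriveriskError):
    """Input data violates a structural precondition (ordering, alignment, ids)."""


class DomainError(DriveriskError):
    """A value is outside the mathematical domain of an operation."""


class ConfigError(DriveriskError):
    """A configuration object is internally inconsistent or out of range."""


class InsufficientDataError(DriveriskError):
    """Too few observations to carry out the requested estimate."""


class CalibrationError(DriveriskError):
    """Probability calibration could not be fitted (e.g. single-class fold)."""


class SearchError(DriveriskError):
    """Every trial of an optimization run failed."""
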