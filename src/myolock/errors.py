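"""Exception and warning types raised by myolock."""


class MyolockError(ValueError):
    """Base class for all myolock errors."""


class InvalidProtocolError(MyolockError):
    """A session protocol has non-positive durations or sampling rate."""


class InvalidParameterError(MyolockError):
    """A parameter is outside its valid range."""


class InvalidInputError(MyolockError):
    """Input data violate an operation's precondition."""


class InvalidConfigurationError(MyolockError):
    """A run configuration is inconsistent with the data."""


class InsufficientBaselineError(MyolockError):
    """Too few rest windows to estimate baseline statistics."""


class IncompleteCalibrationError(MyolockError):
    """Threshold calibration is missing a required motion class."""


class DegenerateTrainingError(MyolockError):
    """Classifier training set cannot support discrimination."""


class CalibrationWarning(UserWarning):
    """Calibration produced thresholds of doubtful usability."""
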