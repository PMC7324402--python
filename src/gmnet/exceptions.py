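"""Exception hierarchy for gmnet."""


class GMNError(Exception):
    """Base class for all gmnet errors."""


class InvalidParameterError(GMNError, ValueError):
    """A parameter violates a documented precondition."""


class DimensionError(GMNError, ValueError):
    """Mismatched state / network / table dimensions."""


class CapacityError(GMNError):
    """Exhaustive enumeration requested beyond the supported module count."""


class RuleParseError(GMNError, ValueError):
    """A rule file could not be parsed; message carries the line number."""


class UnsatisfiableInferenceError(GMNError):
    """No Boolean function within the in-degree bound reproduces the data."""
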