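"""Exception types shared across the package."""


class IAQError(Exception):
    """Base class for package errors."""


class InvalidSchemeError(IAQError):
    """A scheme is missing limits, or a limit is non-positive."""


class IncompleteRecordError(IAQError):
    """A pollutant record is missing one or more of the nine values."""


class CalibrationError(IAQError):
    """The synthetic generator could not satisfy its target labels."""
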