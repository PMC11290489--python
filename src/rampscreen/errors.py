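"""Typed errors shared across the pipeline.

Exit-code mapping for the CLI: ValidationError -> 2, CalibrationError -> 3.
"""


class RampScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(RampScreenError):
    """Malformed input: bad schema, duplicate keys, unresolvable ids, bad config."""


class ConfigurationError(ValidationError):
    """Invalid simulation or pipeline configuration."""


class CalibrationError(RampScreenError):
    """Threshold calibration impossible (e.g. one-class truth set)."""


class DegenerateScaleError(RampScreenError):
    """A scale estimate (MAD or SD) is zero, so standardization is undefined."""
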