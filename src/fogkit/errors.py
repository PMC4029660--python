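"""Exception hierarchy shared across fogkit modules."""


class FogkitError(Exception):
    """Base class for all fogkit errors."""


class FormatError(FogkitError, ValueError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(FogkitError, ValueError):
    """Data violate an invariant (lengths, monotonic time, NaN rows, units)."""


class CalibrationError(FogkitError, RuntimeError):
    """Sagittal-plane or threshold calibration cannot be performed."""


class ParameterError(FogkitError, ValueError):
    """A configuration parameter is out of its admissible range."""
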