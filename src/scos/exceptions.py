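"""Exception types shared across the SCOS processing chain."""


class SCOSError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(SCOSError, ValueError):
    """Input is structurally valid but statistically unusable (empty mask, zero mean...)."""


class SaturationError(SCOSError, ValueError):
    """Requested operating point would saturate the sensor."""


class BaselineError(SCOSError, ValueError):
    """Baseline window is empty, outside the recording, or contains no valid samples."""


class UndefinedCorrelationError(SCOSError, ValueError):
    """Pearson correlation is undefined (constant trace after masking)."""


class FormatError(SCOSError, IOError):
    """On-disk data does not match its declared layout (sidecar/shape/dtype mismatch)."""
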