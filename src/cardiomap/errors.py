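"""Exception hierarchy.

Every error raised on a bad input or an unmeasurable quantity derives from
:class:`CardiomapError`, so callers can catch the package's failures without
masking programming errors.
"""


class CardiomapError(Exception):
    """Base class for all cardiomap errors."""


class ParameterError(CardiomapError, ValueError):
    """Invalid parameter value (non-monotone APD anchors, AR < 1, ...)."""


class UnitError(CardiomapError):
    """Operation requires calibrated (mV) data but got arbitrary units."""


class DegenerateBeatError(CardiomapError):
    """Beat amplitude indistinguishable from the noise floor."""


class UnmeasurableAPDError(CardiomapError):
    """Repolarization level never crossed within the beat window."""


class NotMeasurableError(CardiomapError):
    """Quantity undefined at this sampling interval (upstroke at > 1 ms)."""


class DiastoleError(CardiomapError):
    """No diastolic interval of at least the required length."""


class MetadataError(CardiomapError):
    """Movie metadata sidecar missing or missing required keys."""


class FormatError(CardiomapError):
    """Malformed on-disk recording (frame shape mismatch, bad CSV, ...)."""


class EmptyMaskError(CardiomapError):
    """Preprocessing masked out every pixel."""


class MapError(CardiomapError):
    """Activation map invalid (too few pixels with a detectable upstroke)."""


class UndefinedVelocityError(CardiomapError):
    """Two-point CV with equal activation times at the two sites."""


class ScanError(CardiomapError):
    """Directional CV scan found too few usable directions."""


class InsufficientStimuliError(CardiomapError):
    """Capture assessment needs at least 4 stimuli per recording."""


class DurationError(CardiomapError):
    """Record too short (wave does not traverse the grid, < 1 cycle, ...)."""


class PipelineError(CardiomapError):
    """A pipeline stage failed; carries the stage name and input."""
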