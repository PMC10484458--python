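"""Exception hierarchy shared across the toolkit."""


class CageVitalsError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CageVitalsError):
    """A container on disk is missing pieces or malformed."""


class ValidationError(CageVitalsError):
    """Data violates a structural invariant (e.g. non-monotonic timestamps)."""


class BoundsError(CageVitalsError):
    """An ROI does not fit inside the frame it is applied to."""


class InsufficientDataError(CageVitalsError):
    """Too few samples/frames for the requested computation."""


class InsufficientBinsError(CageVitalsError):
    """A frequency band spans too few spectral bins for a robust noise floor."""


class NyquistError(CageVitalsError):
    """A requested band or simulated rate exceeds the sampling limit."""


class AliasingError(NyquistError):
    """A simulated rate lies above the Nyquist limit of the configured fps."""


class NoFeaturesError(CageVitalsError):
    """No trackable features found inside an ROI."""


class NoAnimalError(CageVitalsError):
    """A segmentation mask is empty where an animal was required."""


class ResolutionError(CageVitalsError):
    """Spatial sampling too coarse to resolve the requested feature."""


class CompressedInputError(CageVitalsError):
    """Lossy-compressed input refused for an SNR-critical pipeline."""


class ConfigurationError(CageVitalsError):
    """Required configuration (e.g. a labeled ROI) is missing or invalid."""
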