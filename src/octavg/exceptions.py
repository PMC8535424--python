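"""Exception hierarchy for the octavg pipeline."""


class OctavgError(Exception):
    """Base class for all pipeline errors."""


class ImageFormatError(OctavgError):
    """Raised when a raster cannot be decoded into a usable angiogram."""


class RegistrationError(OctavgError):
    """Raised when alignment of a frame fails or leaves the sanity bounds."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class DegenerateHistogramError(OctavgError):
    """Raised when automatic thresholding is attempted on a constant image."""


class UndefinedStatisticError(OctavgError):
    """Raised when a statistic is undefined for the given data (zero variance)."""
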