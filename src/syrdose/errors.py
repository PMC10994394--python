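"""Exception hierarchy for the dose-recognition pipeline.

Every stage raises a subclass of :class:`SyrdoseError`; the top-level
``measure_dose`` wraps stage failures in :class:`PipelineError` so callers
(and the CLI) can report which stage broke.
"""


class SyrdoseError(Exception):
    """Base class for all package errors."""


class EmptyInputError(SyrdoseError):
    """Raised for an empty (zero-sized) input image."""


class UnsupportedImageError(SyrdoseError):
    """Raised for rasters with an unsupported channel layout."""


class DegenerateImageError(SyrdoseError):
    """Raised when an image has a single gray level and cannot be split."""


class ThresholdRangeError(SyrdoseError):
    """Raised when a binarization threshold lies outside [0, L-1]."""


class InvalidGaussianError(SyrdoseError):
    """Raised for a non-positive sigma or an even kernel size."""


class ImageTooSmallError(SyrdoseError):
    """Raised when an image is too small for gradient estimation."""


class NoCornersError(SyrdoseError):
    """Raised when the corner response contains no positive peak."""


class LandmarksNotFoundError(SyrdoseError):
    """Raised when the three syringe landmarks cannot be assigned."""


class NoPrincipalAxisError(SyrdoseError):
    """Raised when the silhouette is too isotropic to define a barrel axis."""


class InvalidCapacityError(SyrdoseError):
    """Raised for a non-positive syringe capacity."""


class DegenerateLandmarksError(SyrdoseError):
    """Raised when tip and end vertices coincide."""


class InvalidSceneError(SyrdoseError):
    """Raised for out-of-range synthetic scene parameters."""


class PipelineError(SyrdoseError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
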