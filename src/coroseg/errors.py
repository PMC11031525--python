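"""Named exceptions raised across the pipeline.

Every stage raises a distinct error type so that a failed pipeline run can
report which contract was violated without string matching.
"""


class CorosegError(Exception):
    """Base class for all package errors."""


class VolumeIOError(CorosegError):
    """Base class for volume reading/writing problems."""


class MissingFileError(VolumeIOError):
    """The requested image file does not exist."""


class NotA3DVolumeError(VolumeIOError):
    """The image on disk is not a 3D volume."""


class HeaderError(VolumeIOError):
    """The image header could not be interpreted."""


class InvalidLabelValueError(VolumeIOError):
    """A label map contains a value outside {0, 1, 2}."""


class DegenerateAxisError(CorosegError):
    """A volume axis is too short to resample."""


class ShapeMismatchError(CorosegError):
    """Two grids that must share a shape do not."""


class EmptyCoronaryMaskError(CorosegError):
    """No coronary (label 2) voxels are present."""


class EmptyAortaError(CorosegError):
    """No aortic-root (label 1) voxels where they are required."""


class ComponentCountError(CorosegError):
    """A step requiring exactly two coronary components got another count."""


class AllComponentsRemovedError(CorosegError):
    """The minimum-size filter removed every coronary component."""


class DegenerateAngleError(CorosegError):
    """An origin-angle vector has zero length (ostium at the centroid)."""


class StumpFitError(CorosegError):
    """Decision-stump fitting requires both classes to be present."""


class PhantomGeometryError(CorosegError):
    """Requested phantom geometry does not fit inside the grid."""


class TrainingError(CorosegError):
    """Model training aborted (empty data or non-finite loss)."""


class PipelineStageError(CorosegError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
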