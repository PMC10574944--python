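"""Exception hierarchy shared by the climbkit stages.

Every stage raises a subclass of :class:`ClimbkitError` so that the pipeline
driver can attach the stage name and re-raise without guessing which failures
are domain errors and which are bugs.
"""


class ClimbkitError(Exception):
    """Base class for all domain errors raised by climbkit."""


class SchemaError(ClimbkitError):
    """A skeleton file does not conform to the documented schema."""


class ParseError(ClimbkitError):
    """A file could not be parsed; the message names the offending record."""


class OutOfBoundsError(ClimbkitError):
    """A 2-D keypoint lies outside the depth-grid pixel extent."""


class InsufficientDepthError(ClimbkitError):
    """Fewer than three valid depth nodes surround a keypoint."""


class DegenerateGeometryError(ClimbkitError):
    """A geometric primitive received coincident or zero-length inputs."""


class TooShortError(ClimbkitError):
    """A sequence is too short for the requested operation."""


class ConstantSignalError(ClimbkitError):
    """A signal has zero variance; callers treat this as 'no motion'."""


class DelimitationError(ClimbkitError):
    """Route delimitation failed (no ascent found in the recording)."""


class FitError(ClimbkitError):
    """Plane fitting failed on a degenerate point cloud."""


class ExtractionError(ClimbkitError):
    """Wall-rectangle extraction failed (collinear or too few boundary points)."""


class SingularConfigurationError(ClimbkitError):
    """The wall normal is antiparallel to the camera z-axis; the rotation
    formula is singular and the caller must supply a pre-rotation."""


class ScriptError(ClimbkitError):
    """A synthetic climb script is internally inconsistent."""


class StageError(ClimbkitError):
    """A pipeline stage failed; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
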