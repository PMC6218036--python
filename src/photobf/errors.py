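"""Exception hierarchy for the photographic body-composition pipeline.

Every stage raises a subclass of :class:`PhotoBFError` so callers (and the
CLI) can attach the stage name and subject id without string matching.
"""


class PhotoBFError(Exception):
    """Base class for all pipeline errors."""


class EmptyMaskError(PhotoBFError):
    """No foreground pixels survive chroma keying / cleanup."""


class FramingError(PhotoBFError):
    """Subject is not fully inside the frame (touches image borders)."""


class PoseError(PhotoBFError):
    """Capture pose violated: limbs not separated as the protocol requires."""


class DegenerateSegmentationError(PhotoBFError):
    """A body component came out empty after drawing separation lines."""


class HeightMismatchError(PhotoBFError):
    """Back and side silhouettes disagree on subject height beyond tolerance."""


class DegenerateInputError(PhotoBFError):
    """Input reduces to a degenerate quantity (e.g. zero body volume)."""


class ResolutionError(PhotoBFError):
    """Raster too coarse for the requested measurement."""


class InsufficientSampleError(PhotoBFError):
    """Too few subjects for the requested fit (clustering needs n > 10)."""


class ValidationError(PhotoBFError):
    """A record or vector failed an input contract; message names the field."""
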