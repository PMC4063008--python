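"""Exception hierarchy for the foveastrain pipeline."""


class FoveastrainError(Exception):
    """Base class for all pipeline errors."""


class NoPupilFound(FoveastrainError):
    """Ring contrast below the configured floor: closed eye or bad frame."""


class RefinementFailed(FoveastrainError):
    """No connected component survived size filtering during pupil refinement."""


class SRCountError(FoveastrainError):
    """Number of detected specular reflections differs from four."""


class DegenerateQuad(FoveastrainError):
    """SR quadrilateral is (near-)collinear; projective transform not invertible."""


class ShapeError(FoveastrainError):
    """Raster shapes incompatible with the requested operation."""


class ChannelError(FoveastrainError):
    """Input does not have the expected number of color channels."""


class ZeroImage(FoveastrainError):
    """Brightness normalization undefined: zero-mean reference image."""


class GridMismatch(FoveastrainError):
    """Two window series were built on different window/step grids."""


class DegenerateInput(FoveastrainError):
    """Statistical input without variation (constant series, zero differences)."""


class DegenerateDesign(FoveastrainError):
    """2^k factorial design with zero total sum of squares; ratios undefined."""


class ZeroSpread(FoveastrainError):
    """Cohen's d undefined: both groups have zero standard deviation."""


class SpecError(FoveastrainError):
    """Invalid synthetic scene specification."""
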