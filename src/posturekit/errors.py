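"""Exception hierarchy shared across the pipeline stages."""


class PostureKitError(Exception):
    """Base class for all posturekit errors."""


class DegenerateCoverage(PostureKitError):
    """Magnetometer calibration samples do not span enough directions."""


class StillIntervalTooShort(PostureKitError):
    """A still interval shorter than the minimum needed for bias/offset estimation."""


class NotStatic(PostureKitError):
    """Accelerometer norm too far from 1 g for a static attitude estimate."""


class ZeroVector(PostureKitError):
    """An input vector that must be non-zero has zero norm."""


class NonMonotoneTime(PostureKitError):
    """Timestamps are not strictly increasing."""


class MissingSegmentPose(PostureKitError):
    """A body segment has no orientation track and no segment to inherit from."""


class TooShort(PostureKitError):
    """Time series shorter than a single analysis window."""


class TooFewPoints(PostureKitError):
    """Fewer samples than the interpolation scheme requires."""


class EmptyClass(PostureKitError):
    """A task class contributes no windows to the dataset."""


class InsufficientSamplesPerClass(PostureKitError):
    """Not enough samples per class for the requested stratified split."""


class MalformedCsv(PostureKitError):
    """A node CSV is missing required columns or contains unparseable values."""


class UnitMismatch(PostureKitError):
    """A node CSV header declares units other than g / deg/s / gauss."""


class CalibrationMissing(PostureKitError):
    """A pipeline stage needs a calibration file that does not exist."""


class PipelineStageError(PostureKitError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
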