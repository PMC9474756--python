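"""Exception hierarchy for tbmoco."""


class TbmocoError(Exception):
    """Base class for all tbmoco errors."""


class InvalidArgumentError(TbmocoError, ValueError):
    """A precondition on an argument was violated."""


class FormatError(TbmocoError, ValueError):
    """An on-disk file does not match the expected format."""


class NoReferenceFrameError(TbmocoError, ValueError):
    """No frame of the schedule ends by the requested cut time."""


class UndefinedMetricError(TbmocoError, ValueError):
    """A similarity metric is undefined for the given inputs (e.g. zero variance)."""


class SegmentationError(TbmocoError, ValueError):
    """A segmentation step produced an empty or invalid mask."""
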