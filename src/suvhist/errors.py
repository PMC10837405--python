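"""Exception and warning types shared across the package."""


class SuvhistError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SuvhistError, ValueError):
    """An input violates a documented precondition."""


class DimensionalityError(ValidationError):
    """An image does not have exactly three spatial dimensions."""


class EmptyROIError(SuvhistError):
    """A region of interest contains no voxels."""


class GridMismatchError(SuvhistError):
    """Volume and mask live on different grids; resample the mask first."""


class PlacementError(SuvhistError):
    """A requested ROI placement falls outside the image volume."""


class UndefinedRatioError(SuvhistError):
    """A ratio denominator (e.g. reference-region maximum) is zero."""


class UndefinedStatisticWarning(UserWarning):
    """A statistic is undefined for this input (e.g. zero variance)."""


class DegenerateThresholdWarning(UserWarning):
    """Two groups are indistinguishable; no meaningful cut exists."""


class PlacementWarning(UserWarning):
    """An ROI placement is degenerate but proceeds (e.g. midline lesion)."""


class OutOfRangeWarning(UserWarning):
    """Values fall outside the fixed histogram display range."""
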