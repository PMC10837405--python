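"""Traditional metabolic and first-order histogram features of a lesion.

Traditional parameters
----------------------
* ``SUVmax`` / ``SUVmean`` / ``SUVmedian`` — extrema/central tendency of the
  ROI voxel SUVs.
* ``MTV`` (metabolic tumor volume, mL) = Np x voxel volume.
* ``TLA`` (total lesion activity, mL.SUV) = SUVmean x MTV, algebraically the
  voxel-volume-weighted sum of all SUVs.
* ``T/N`` — SUVmax of the lesion over Nmax of pooled contralateral
  reference spheres.

Histogram parameters
--------------------
The ROI voxel SUVs form a number series X(i), i = 1..Np.  Neoplastic uptake
is approximately normally distributed over the lesion, while non-neoplastic
(necrotic/inflammatory) uptake piles up near the background and is
positively skewed.  Two scalars quantify this:

    skewness = (1/Np * sum (X(i) - Xbar)^3) / (sqrt(1/Np * sum (X(i) - Xbar)^2))^3
    tendency = SUVmean - SUVmedian

Skewness is the *population* (divide-by-Np) third standardized moment, with
no small-sample correction — the definition is intentionally exact so that
values are comparable across software.  Both are computed from raw voxels,
never from binned histogram counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import (
    EmptyROIError,
    OutOfRangeWarning,
    UndefinedRatioError,
    UndefinedStatisticWarning,
    ValidationError,
)
from .roi import VoxelSeries

__all__ = [
    "LesionFeatures",
    "HistogramSummary",
    "skewness",
    "tendency",
    "traditional_features",
    "lesion_features",
    "histogram",
    "FEATURE_COLUMNS",
]

#: Canonical feature column order for CSV/report output.
FEATURE_COLUMNS = (
    "suv_max",
    "suv_mean",
    "suv_median",
    "mtv",
    "tla",
    "tn_ratio",
    "n_max",
    "n_mean",
    "skewness",
    "tendency",
)


@dataclass(frozen=True)
class LesionFeatures:
    """All quantitative parameters of one lesion ROI.

    Units: ``mtv`` in mL, ``tla`` in mL.SUV, ``tendency`` in SUV; the rest
    are dimensionless (SUV convention).
    """

    suv_max: float
    suv_mean: float
    suv_median: float
    mtv: float
    tla: float
    tn_ratio: float
    n_max: float
    n_mean: float
    skewness: float
    tendency: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class HistogramSummary:
    """Display histogram of ROI voxel SUVs over a fixed range.

    ``normal_fit`` holds the moment-matched Gaussian (sample mean,
    population SD) used to overlay a normal curve on the plot.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    normal_fit: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def _values(series: VoxelSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, VoxelSeries):
        return series.values
    arr = np.asarray(series, dtype=np.float64).ravel()
    if arr.size == 0:
        raise EmptyROIError("empty value series")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("series contains non-finite values")
    return arr


def skewness(series: VoxelSeries | np.ndarray) -> float:
    """Population third standardized moment of the voxel series.

    Returns NaN (with :class:`UndefinedStatisticWarning`) when the series
    has zero variance; requires Np >= 2.
    """
    x = _values(series)
    if x.size < 2:
        raise ValidationError(f"skewness requires Np >= 2, got Np = {x.size}")
    centered = x - x.mean()
    m2 = np.mean(centered**2)
    if m2 == 0:
        warnings.warn(
            "skewness undefined for a zero-variance series; returning NaN",
            UndefinedStatisticWarning,
            stacklevel=2,
        )
        return float("nan")
    m3 = np.mean(centered**3)
    return float(m3 / m2**1.5)


def tendency(series: VoxelSeries | np.ndarray) -> float:
    """SUVmean - SUVmedian (even Np: median is the central midpoint)."""
    x = _values(series)
    return float(x.mean() - np.median(x))


def traditional_features(
    lesion: VoxelSeries, reference: VoxelSeries
) -> dict[str, float]:
    """The five traditional parameters plus reference-region statistics.

    ``reference`` is the pooled voxel series of all reference spheres
    (single Nmax/Nmean values imply pooling the three spheres).
    """
    x = lesion.values
    n = reference.values
    suv_max = float(x.max())
    suv_mean = float(x.mean())
    mtv = lesion.n_voxels * lesion.voxel_volume
    n_max = float(n.max())
    if n_max == 0:
        raise UndefinedRatioError("reference Nmax is zero; T/N ratio undefined")
    return {
        "suv_max": suv_max,
        "suv_mean": suv_mean,
        "suv_median": float(np.median(x)),
        "mtv": mtv,
        "tla": suv_mean * mtv,
        "tn_ratio": suv_max / n_max,
        "n_max": n_max,
        "n_mean": float(n.mean()),
    }


def lesion_features(lesion: VoxelSeries, reference: VoxelSeries) -> LesionFeatures:
    """Full feature set (traditional + histogram) for one lesion ROI."""
    feats = traditional_features(lesion, reference)
    feats["skewness"] = skewness(lesion)
    feats["tendency"] = tendency(lesion)
    return LesionFeatures(**feats)


def histogram(
    series: VoxelSeries | np.ndarray,
    bins: int = 64,
    value_range: tuple[float, float] = (0.0, 4.0),
) -> HistogramSummary:
    """Voxel-value histogram over a fixed display range (default SUV 0-4).

    Values outside the range accumulate into the terminal bins (with a
    warning) so that counts always sum to Np.  The bin count is a display
    knob only — skewness and tendency are computed from raw voxels.
    """
    if bins < 2:
        raise ValidationError(f"need at least 2 bins, got {bins}")
    lo, hi = value_range
    if not (hi > lo):
        raise ValidationError(f"invalid histogram range {value_range}")
    x = _values(series)
    if np.any((x < lo) | (x > hi)):
        warnings.warn(
            f"{int(np.sum((x < lo) | (x > hi)))} voxel(s) outside the display "
            f"range [{lo}, {hi}]; accumulated into the terminal bins",
            OutOfRangeWarning,
            stacklevel=2,
        )
    counts, edges = np.histogram(np.clip(x, lo, hi), bins=bins, range=(lo, hi))
    fit = {"mu": float(x.mean()), "sigma": float(np.sqrt(np.mean((x - x.mean()) ** 2)))}
    return HistogramSummary(bin_edges=edges, counts=counts, normal_fit=fit)
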