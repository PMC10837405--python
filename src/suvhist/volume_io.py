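"""Volumetric image I/O and SUV-map construction.

An SUV (standard uptake value) map expresses tissue activity concentration
normalized by injected dose per body weight,

    SUV(v) = C(v) [Bq/mL] * body_weight [g] / (injected_dose [Bq] * decay_factor),

which is dimensionless under the conventional 1 g/mL tissue-density
assumption.  The decay factor is an explicit input in (0, 1]: whether the
dose is corrected to injection or to scan-start time is an acquisition-site
convention, so it is never computed internally from a half-life.

All volumes carry a 4x4 grid-index -> world-mm affine (NIfTI RAS+).  Voxel
volume in mL is derived from the affine determinant and never stored
independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, ValidationError

__all__ = [
    "AcquisitionMeta",
    "SUVVolume",
    "read_volume",
    "activity_to_suv",
    "write_suv_volume",
    "read_acquisition_meta",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection metadata needed to scale raw activity into SUV.

    Parameters
    ----------
    body_weight_kg : float
        Patient body weight in kilograms, > 0.
    injected_dose_mbq : float
        Injected activity in MBq, > 0.  (The tracer protocol modeled here
        injects 3.7 MBq/kg.)
    decay_factor : float
        Dimensionless decay correction in (0, 1], applied to the dose.
    frame : str
        Free-text label for the acquisition frame, e.g. "30min-static".
    """

    body_weight_kg: float
    injected_dose_mbq: float
    decay_factor: float = 1.0
    frame: str = ""

    def __post_init__(self) -> None:
        if not (self.body_weight_kg > 0):
            raise ValidationError(f"body_weight_kg must be > 0, got {self.body_weight_kg}")
        if not (self.injected_dose_mbq > 0):
            raise ValidationError(f"injected_dose_mbq must be > 0, got {self.injected_dose_mbq}")
        if not (0 < self.decay_factor <= 1):
            raise ValidationError(f"decay_factor must be in (0, 1], got {self.decay_factor}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "body_weight_kg": self.body_weight_kg,
            "injected_dose_MBq": self.injected_dose_mbq,
            "decay_factor": self.decay_factor,
            "frame": self.frame,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionMeta":
        payload = json.loads(Path(path).read_text())
        return cls(
            body_weight_kg=payload["body_weight_kg"],
            injected_dose_mbq=payload["injected_dose_MBq"],
            decay_factor=payload.get("decay_factor", 1.0),
            frame=payload.get("frame", ""),
        )


def read_acquisition_meta(path: str | Path) -> AcquisitionMeta:
    """Read an :class:`AcquisitionMeta` JSON sidecar."""
    return AcquisitionMeta.from_json(path)


@dataclass
class SUVVolume:
    """A 3D scalar volume in SUV units on a world-anchored grid.

    ``data`` is stored float64; ``affine`` maps grid indices to world mm
    (RAS+).  Values must be finite and non-negative (SUV is non-negative by
    construction).
    """

    data: np.ndarray
    affine: np.ndarray
    meta: AcquisitionMeta | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {self.affine.shape}")
        det = np.linalg.det(self.affine[:3, :3])
        if det == 0 or not np.isfinite(det):
            raise ValidationError("affine spatial part is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise ValidationError("volume contains negative values; SUV is non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mL (|det| of the spatial affine, mm^3 -> mL)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])) / 1000.0)

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """World-coordinate bounding box of all voxel centers (min, max)."""
        shape = np.array(self.shape, dtype=float)
        corners_idx = np.array(
            [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
        )
        corners = nib.affines.apply_affine(self.affine, corners_idx)
        return corners.min(axis=0), corners.max(axis=0)


def read_volume(path: str | Path) -> SUVVolume:
    """Read a NIfTI-1/2 volume from disk.

    The on-disk scale slope/intercept are applied, so ``data`` matches the
    stored physical values.  Raises :class:`DimensionalityError` for non-3D
    images and ``IOError`` (with the path in the message) for unreadable
    files.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got {data.ndim} dimensions"
        )
    return SUVVolume(data=data, affine=np.asarray(img.affine))


def activity_to_suv(
    activity: np.ndarray | SUVVolume,
    meta: AcquisitionMeta,
    affine: np.ndarray | None = None,
) -> SUVVolume:
    """Convert an activity-concentration volume (Bq/mL) into an SUV map.

    SUV(v) = activity(v) * body_weight[g] / (injected_dose[Bq] * decay_factor).

    ``activity`` may be a raw 3D array (with ``affine`` supplied) or a
    volume object whose affine is reused.
    """
    if isinstance(activity, SUVVolume):
        arr, aff = activity.data, activity.affine
    else:
        arr = np.asarray(activity, dtype=np.float64)
        if affine is None:
            affine = np.eye(4)
        aff = np.asarray(affine, dtype=np.float64)
    weight_g = meta.body_weight_kg * 1000.0
    dose_bq = meta.injected_dose_mbq * 1e6
    suv = arr * weight_g / (dose_bq * meta.decay_factor)
    return SUVVolume(data=suv, affine=aff, meta=meta)


def write_suv_volume(vol: SUVVolume, path: str | Path) -> None:
    """Write an SUV volume to NIfTI (float32 payload, affine bit-exact).

    PET dynamic range (SUV roughly 0-30) makes float32 storage lossless in
    practice.  Negative or non-finite voxels fail validation before any
    bytes are written.
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValidationError("refusing to write non-finite voxel values")
    if np.any(vol.data < 0):
        raise ValidationError("refusing to write negative SUV values")
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_data_dtype(np.float32)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write volume {path}: {exc}") from exc
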