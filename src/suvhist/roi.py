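"""Lesion and reference regions of interest.

The lesion ROI is delineated on the anatomical (MRI) grid and applied to the
co-registered PET volume; reference regions are 1-cm spheres placed in
contralateral normal brain, mirroring the lesion position across the
midsagittal plane.  Everything here operates in world millimetres through
the image affines — voxel indices never cross a module boundary.

Membership rule: a voxel belongs to a region iff its *center* lies inside
(images are never resampled; binary masks are resampled nearest-neighbor
when grids differ, so features are always computed on the native PET grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    EmptyROIError,
    GridMismatchError,
    PlacementError,
    PlacementWarning,
    ValidationError,
)
from .volume_io import SUVVolume

__all__ = [
    "BinaryMask",
    "SphereROI",
    "VoxelSeries",
    "read_mask",
    "write_mask",
    "rasterize_sphere",
    "mirror_spheres",
    "resample_mask",
    "extract_voxels",
    "union_masks",
]

#: Default superior-inferior offsets (mm) used to disperse mirrored
#: reference spheres so they do not coincide.  The dispersal scheme is a
#: package convention; sphere centers may always be given explicitly.
DEFAULT_SPHERE_OFFSETS_MM = (0.0, 12.0, -12.0)


@dataclass
class BinaryMask:
    """A boolean 3D mask bound to a world frame by its affine."""

    data: np.ndarray
    affine: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(f"mask must be 3D, got {self.data.ndim} dimensions")
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def centroid_world(self) -> np.ndarray:
        """World-mm centroid of the true voxels."""
        if self.n_voxels == 0:
            raise EmptyROIError(f"mask {self.label!r} is empty")
        idx = np.argwhere(self.data).astype(float)
        return nib.affines.apply_affine(self.affine, idx.mean(axis=0))


@dataclass(frozen=True)
class SphereROI:
    """A spherical ROI defined in world coordinates (center mm, diameter mm)."""

    center: tuple[float, float, float]
    diameter: float = 10.0

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValidationError(f"sphere diameter must be > 0, got {self.diameter}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass
class VoxelSeries:
    """The ordered multiset X(i), i = 1..Np, of SUVs inside one ROI.

    This is the substrate of every feature: order is ascending linear
    (C-scan) index, fixed for reproducibility although all downstream
    statistics are order-invariant.
    """

    values: np.ndarray
    voxel_volume: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise EmptyROIError("voxel series is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("voxel series contains non-finite values")
        if not (self.voxel_volume > 0):
            raise ValidationError(f"voxel_volume must be > 0, got {self.voxel_volume}")

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI mask; any nonzero voxel is inside."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: mask must be 3D, got {data.ndim} dimensions")
    return BinaryMask(data=data != 0, affine=np.asarray(img.affine), label=path.stem)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI (1 = inside)."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def _index_bounding_box(
    grid: SUVVolume, lo_world: np.ndarray, hi_world: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Conservative voxel-index AABB covering a world-space box.

    The preimage of a world AABB under an affine map is a parallelepiped;
    its index-space AABB (from the 8 mapped corners) therefore covers the
    whole region even for oblique affines.
    """
    corners = np.array(
        [[x, y, z] for x in (lo_world[0], hi_world[0])
         for y in (lo_world[1], hi_world[1])
         for z in (lo_world[2], hi_world[2])]
    )
    idx = nib.affines.apply_affine(np.linalg.inv(grid.affine), corners)
    lo = np.floor(idx.min(axis=0)).astype(int)
    hi = np.ceil(idx.max(axis=0)).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(grid.shape))
    if np.any(lo >= hi):
        return None
    return lo, hi


def rasterize_sphere(sphere: SphereROI, grid: SUVVolume) -> BinaryMask:
    """Rasterize a world-coordinate sphere onto a volume's grid.

    A voxel is inside iff its world-coordinate center lies within
    ``diameter / 2`` of the sphere center (inclusive boundary).
    """
    center = np.asarray(sphere.center, dtype=float)
    r = sphere.diameter / 2.0
    mask = np.zeros(grid.shape, dtype=bool)
    box = _index_bounding_box(grid, center - r, center + r)
    if box is not None:
        lo, hi = box
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        world = nib.affines.apply_affine(grid.affine, idx)
        inside = np.linalg.norm(world - center, axis=1) <= r
        mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = True
    if not mask.any():
        raise EmptyROIError(
            f"sphere at {tuple(center)} (d={sphere.diameter} mm) contains no voxel center"
        )
    return BinaryMask(data=mask, affine=grid.affine, label="sphere")


def mirror_spheres(
    lesion_mask: BinaryMask,
    grid: SUVVolume,
    n: int = 3,
    offsets: list[tuple[float, float, float]] | None = None,
    x_mid: float | None = None,
    diameter: float = 10.0,
) -> list[SphereROI]:
    """Place reference spheres contralateral to the lesion.

    The lesion centroid is reflected across the midsagittal plane
    (world x = ``x_mid``, defaulting to the volume's world-x midpoint), and
    the given superior-inferior offsets disperse ``n`` non-identical
    spheres around the reflected point.
    """
    if lesion_mask.n_voxels == 0:
        raise EmptyROIError("lesion mask is empty; cannot mirror")
    if n < 1:
        raise ValidationError(f"need n >= 1 spheres, got {n}")
    centroid = lesion_mask.centroid_world()
    lo, hi = grid.world_extent()
    if x_mid is None:
        x_mid = float((lo[0] + hi[0]) / 2.0)
    if abs(centroid[0] - x_mid) < 1e-9:
        warnings.warn(
            "lesion centroid lies on the midsagittal plane; mirrored spheres "
            "coincide with the lesion position",
            PlacementWarning,
            stacklevel=2,
        )
    reflected = centroid.copy()
    reflected[0] = 2.0 * x_mid - centroid[0]
    if offsets is None:
        base = list(DEFAULT_SPHERE_OFFSETS_MM)
        k = 2
        while len(base) < n:  # extend the ladder: 0, ±12, ±24, ...
            base.extend([12.0 * k, -12.0 * k])
            k += 1
        offs = [(0.0, 0.0, dz) for dz in base[:n]]
    else:
        if len(offsets) < n:
            raise ValidationError(f"{len(offsets)} offsets given for n={n} spheres")
        offs = [tuple(map(float, o)) for o in offsets[:n]]
    spheres = []
    for off in offs:
        c = reflected + np.asarray(off)
        if np.any(c < lo) or np.any(c > hi):
            raise PlacementError(
                f"mirrored sphere center {tuple(np.round(c, 2))} falls outside "
                f"the volume extent"
            )
        spheres.append(SphereROI(center=tuple(c), diameter=diameter))
    return spheres


def _same_grid(a_affine: np.ndarray, a_shape: tuple, b_affine: np.ndarray, b_shape: tuple) -> bool:
    return a_shape == b_shape and np.allclose(a_affine, b_affine, atol=1e-9)


def resample_mask(mask: BinaryMask, target: SUVVolume) -> BinaryMask:
    """Resample a binary mask onto a target grid (nearest neighbor).

    Each target voxel center is mapped through world coordinates to the
    source grid; the voxel is inside iff the nearest source voxel is.
    Identity when the grids already coincide.  Nearest-neighbor keeps the
    mask binary; images themselves are never resampled.
    """
    if _same_grid(mask.affine, mask.data.shape, target.affine, target.shape):
        return BinaryMask(data=mask.data.copy(), affine=mask.affine.copy(), label=mask.label)
    # target index -> world -> source index, evaluated with order-0 splines
    xform = np.linalg.inv(mask.affine) @ target.affine
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in target.shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)], axis=0)
    src = (xform @ idx)[:3]
    out = ndimage.map_coordinates(
        mask.data.astype(np.float32), src, order=0, mode="constant", cval=0.0
    )
    data = out.reshape(target.shape) > 0.5
    if not data.any():
        raise EmptyROIError(
            f"mask {mask.label!r} resampled to the target grid is empty "
            "(disjoint world extents?)"
        )
    return BinaryMask(data=data, affine=target.affine.copy(), label=mask.label)


def extract_voxels(vol: SUVVolume, mask: BinaryMask, label: str | None = None) -> VoxelSeries:
    """Extract the SUV number series of all voxels inside a mask.

    The mask must live on the volume's grid (resample first if not); the
    scan order is ascending linear index.
    """
    if not _same_grid(mask.affine, mask.data.shape, vol.affine, vol.shape):
        raise GridMismatchError(
            "mask and volume are on different grids; call resample_mask first"
        )
    if mask.n_voxels == 0:
        raise EmptyROIError(f"mask {mask.label!r} is empty")
    values = vol.data[mask.data]  # boolean indexing yields C-scan order
    return VoxelSeries(
        values=values,
        voxel_volume=vol.voxel_volume,
        label=label if label is not None else mask.label,
    )


def union_masks(masks: list[BinaryMask], label: str = "union") -> BinaryMask:
    """Union of masks on a common grid (e.g. pooling reference spheres)."""
    if not masks:
        raise ValidationError("union of zero masks")
    first = masks[0]
    data = first.data.copy()
    for m in masks[1:]:
        if not _same_grid(m.affine, m.data.shape, first.affine, first.data.shape):
            raise GridMismatchError("all masks in a union must share one grid")
        data |= m.data
    return BinaryMask(data=data, affine=first.affine.copy(), label=label)
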