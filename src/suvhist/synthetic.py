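"""Synthetic PET phantoms with known histogram ground truth.

Patient images behind the published cohort statistics are not available, so
the pipeline is exercised on digital phantoms that reproduce the
*statistical* structure the analysis rests on:

* a low, uniform normal-brain background (SUV ~ 0.1), giving
  tumor-to-normal ratios near 20;
* spherical lesions of a few to tens of mL whose voxel SUVs are drawn
  i.i.d. from a chosen intensity law — Gaussian for neoplastic lesions
  (symmetric histogram, population skewness 0), shifted gamma for
  non-neoplastic lesions (positively skewed, population skewness
  2/sqrt(shape) in closed form);
* optionally a two-compartment ring + core lesion whose whole-lesion
  histogram is the bimodal mixture of the two compartments.

The gamma family was chosen over e.g. the skew-normal precisely because its
population skewness is closed-form, which turns every phantom into an exact
parameter-recovery oracle.  Voxels are i.i.d. (no spatial texture): all
features downstream are order-invariant, so spatial correlation would add
realism but no testable signal.  Laws are clipped at zero after sampling;
defaults keep P(X < 0) around 1e-4 so the perturbation of the truth
skewness is far below sampling error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyROIError, PlacementError, ValidationError
from .roi import BinaryMask, SphereROI, mirror_spheres, rasterize_sphere, write_mask
from .volume_io import SUVVolume, write_suv_volume

__all__ = [
    "GaussianLaw",
    "GammaLaw",
    "MixtureLaw",
    "PhantomSpec",
    "SyntheticSubject",
    "make_phantom",
    "make_ring_core_phantom",
    "make_cohort",
    "default_affine",
]

# Cohort calibration constants (group sizes and law centers chosen to match
# the modeled study's printed summary statistics: SUVmax ~ 2.5, T/N ~ 20,
# non-neoplastic population skewness ~ 0.94 = 2/sqrt(4.57)).
DEFAULT_N_NEOPLASTIC = 18
DEFAULT_N_NONNEOPLASTIC = 3
NEOPLASTIC_MU = 1.3
NEOPLASTIC_SIGMA = 0.35
NONNEOPLASTIC_SHAPE = 4.57
NONNEOPLASTIC_MEAN = 0.9
BACKGROUND_MEAN = 0.1
BACKGROUND_SD = 0.01


class IntensityLaw:
    """Base class: a scalar law with closed-form first three raw moments."""

    def raw_moments(self) -> tuple[float, float, float]:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raise NotImplementedError

    @property
    def mean(self) -> float:
        return self.raw_moments()[0]

    @property
    def population_skewness(self) -> float:
        m1, m2, m3 = self.raw_moments()
        mu2 = m2 - m1**2
        mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
        if mu2 <= 0:
            return float("nan")
        return float(mu3 / mu2**1.5)


@dataclass(frozen=True)
class GaussianLaw(IntensityLaw):
    """Normal law N(mu, sigma^2): population skewness exactly 0."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValidationError(f"gaussian sigma must be > 0, got {self.sigma}")

    def raw_moments(self) -> tuple[float, float, float]:
        m, s2 = self.mu, self.sigma**2
        return (m, m**2 + s2, m**3 + 3 * m * s2)

    @property
    def population_skewness(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size=n)


@dataclass(frozen=True)
class GammaLaw(IntensityLaw):
    """Shifted gamma law: population skewness 2 / sqrt(shape), closed form."""

    shape: float
    scale: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if not (self.shape > 0) or not (self.scale > 0):
            raise ValidationError("gamma shape and scale must be > 0")

    @classmethod
    def from_mean(cls, shape: float, mean: float, shift: float = 0.0) -> "GammaLaw":
        """Gamma law with given shape and target mean (above the shift)."""
        return cls(shape=shape, scale=(mean - shift) / shape, shift=shift)

    def raw_moments(self) -> tuple[float, float, float]:
        k, t, s = self.shape, self.scale, self.shift
        g1 = k * t
        g2 = k * (k + 1) * t**2
        g3 = k * (k + 1) * (k + 2) * t**3
        return (
            s + g1,
            s**2 + 2 * s * g1 + g2,
            s**3 + 3 * s**2 * g1 + 3 * s * g2 + g3,
        )

    @property
    def population_skewness(self) -> float:
        return float(2.0 / np.sqrt(self.shape))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.shift + rng.gamma(self.shape, self.scale, size=n)


@dataclass(frozen=True)
class MixtureLaw(IntensityLaw):
    """Finite mixture; skewness follows from weighted raw moments."""

    components: tuple[IntensityLaw, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights) or not self.components:
            raise ValidationError("components and weights must align and be non-empty")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValidationError(f"mixture weights must sum to 1, got {sum(self.weights)}")
        if any(w < 0 for w in self.weights):
            raise ValidationError("mixture weights must be non-negative")

    def raw_moments(self) -> tuple[float, float, float]:
        moments = np.array([c.raw_moments() for c in self.components])
        w = np.asarray(self.weights)
        return tuple(float(v) for v in w @ moments)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        counts = rng.multinomial(n, self.weights)
        parts = [c.sample(rng, k) for c, k in zip(self.components, counts)]
        out = np.concatenate(parts)
        rng.shuffle(out)
        return out


def default_affine(
    grid_shape: tuple[int, int, int], voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """RAS+ affine placing the world origin at the volume center."""
    vs = np.asarray(voxel_size, dtype=float)
    shape = np.asarray(grid_shape, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -(shape - 1) / 2.0 * vs
    return affine


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic subject.

    The default 96 x 96 x 60 grid at 2 mm isotropic gives ~1800-voxel
    lesions for the default 15-mm radius (MTV ~14 mL) at seconds-scale
    generation cost.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 60)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_mean: float = BACKGROUND_MEAN
    background_sd: float = BACKGROUND_SD
    lesion_center: tuple[float, float, float] = (30.0, 0.0, 0.0)
    lesion_radius: float = 15.0
    law: IntensityLaw = field(default_factory=lambda: GaussianLaw(NEOPLASTIC_MU, NEOPLASTIC_SIGMA))
    group: str = "neoplastic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lesion_radius > 0):
            raise ValidationError(f"lesion radius must be > 0, got {self.lesion_radius}")
        if not (self.background_sd >= 0):
            raise ValidationError("background_sd must be >= 0")


@dataclass
class SyntheticSubject:
    """A generated subject with its ground truth attached."""

    subject_id: str
    suv_volume: SUVVolume
    lesion_mask: BinaryMask
    reference_spheres: list[SphereROI]
    truth: dict
    sub_masks: dict[str, BinaryMask] | None = None


def _blank_volume(spec: PhantomSpec, rng: np.random.Generator) -> SUVVolume:
    affine = default_affine(spec.grid_shape, spec.voxel_size)
    bg = rng.normal(spec.background_mean, spec.background_sd, size=spec.grid_shape)
    return SUVVolume(data=np.clip(bg, 0.0, None), affine=affine)


def _lesion_mask(spec: PhantomSpec, vol: SUVVolume, radius: float, label: str) -> BinaryMask:
    sphere = SphereROI(center=spec.lesion_center, diameter=2.0 * radius)
    lo, hi = vol.world_extent()
    c = np.asarray(spec.lesion_center)
    if np.any(c - radius < lo) or np.any(c + radius > hi):
        raise PlacementError(
            f"lesion (center {tuple(c)}, r={radius} mm) extends outside the grid"
        )
    try:
        mask = rasterize_sphere(sphere, vol)
    except EmptyROIError as exc:
        raise PlacementError(str(exc)) from exc
    mask.label = label
    return mask


def make_phantom(spec: PhantomSpec) -> SyntheticSubject:
    """Generate one single-compartment phantom.

    Background voxels follow a zero-truncated normal; lesion voxels are
    i.i.d. draws from ``spec.law`` clipped at zero.  Bit-reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    vol = _blank_volume(spec, rng)
    mask = _lesion_mask(spec, vol, spec.lesion_radius, "lesion")
    vol.data[mask.data] = np.clip(spec.law.sample(rng, mask.n_voxels), 0.0, None)
    spheres = mirror_spheres(mask, vol)
    return SyntheticSubject(
        subject_id=f"phantom-{spec.seed}",
        suv_volume=vol,
        lesion_mask=mask,
        reference_spheres=spheres,
        truth={
            "group": spec.group,
            "population_skewness": spec.law.population_skewness,
            "law": repr(spec.law),
            "seed": spec.seed,
        },
    )


def make_ring_core_phantom(
    spec: PhantomSpec,
    inner_radius: float,
    core_law: IntensityLaw,
) -> SyntheticSubject:
    """Generate a two-compartment (ring + core) phantom.

    ``spec.law`` fills the outer ring (e.g. proliferating rim, Gaussian);
    ``core_law`` fills the core (e.g. necrosis, gamma).  The whole-lesion
    histogram is then the voxel-count-weighted mixture of the two laws —
    the mechanism behind dual-peaked lesion histograms.
    """
    if not (0 < inner_radius < spec.lesion_radius):
        raise ValidationError(
            f"need 0 < inner_radius < lesion_radius, got {inner_radius} vs {spec.lesion_radius}"
        )
    rng = np.random.default_rng(spec.seed)
    vol = _blank_volume(spec, rng)
    lesion = _lesion_mask(spec, vol, spec.lesion_radius, "lesion")
    core = _lesion_mask(spec, vol, inner_radius, "core")
    ring = BinaryMask(data=lesion.data & ~core.data, affine=vol.affine, label="ring")
    vol.data[ring.data] = np.clip(spec.law.sample(rng, ring.n_voxels), 0.0, None)
    vol.data[core.data] = np.clip(core_law.sample(rng, core.n_voxels), 0.0, None)
    w_ring = ring.n_voxels / lesion.n_voxels
    mixture = MixtureLaw(components=(spec.law, core_law), weights=(w_ring, 1.0 - w_ring))
    spheres = mirror_spheres(lesion, vol)
    return SyntheticSubject(
        subject_id=f"ringcore-{spec.seed}",
        suv_volume=vol,
        lesion_mask=lesion,
        reference_spheres=spheres,
        sub_masks={"ring": ring, "core": core},
        truth={
            "group": spec.group,
            "population_skewness": mixture.population_skewness,
            "ring_population_skewness": spec.law.population_skewness,
            "core_population_skewness": core_law.population_skewness,
            "seed": spec.seed,
        },
    )


def _neoplastic_spec(seed: int, rng: np.random.Generator) -> PhantomSpec:
    # lognormal jitter spreads per-subject SUVmax around ~2.5
    mu = NEOPLASTIC_MU * np.exp(rng.normal(0.0, 0.15))
    sigma = NEOPLASTIC_SIGMA * np.exp(rng.normal(0.0, 0.15))
    radius = rng.uniform(10.0, 20.0)
    center = (30.0, rng.uniform(-10.0, 10.0), rng.uniform(-10.0, 10.0))
    return PhantomSpec(
        lesion_center=center,
        lesion_radius=radius,
        law=GaussianLaw(mu, sigma),
        group="neoplastic",
        seed=seed,
    )


def _nonneoplastic_spec(seed: int, rng: np.random.Generator) -> PhantomSpec:
    shape = NONNEOPLASTIC_SHAPE * np.exp(rng.normal(0.0, 0.25))
    mean = NONNEOPLASTIC_MEAN * np.exp(rng.normal(0.0, 0.1))
    radius = rng.uniform(10.0, 20.0)
    center = (30.0, rng.uniform(-10.0, 10.0), rng.uniform(-10.0, 10.0))
    return PhantomSpec(
        lesion_center=center,
        lesion_radius=radius,
        law=GammaLaw.from_mean(shape, mean),
        group="non-neoplastic",
        seed=seed,
    )


def make_cohort(
    n_neoplastic: int = DEFAULT_N_NEOPLASTIC,
    n_nonneoplastic: int = DEFAULT_N_NONNEOPLASTIC,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate a full synthetic cohort (default 18 neoplastic vs 3 not).

    Per-subject law parameters are lognormally jittered around the group
    calibration constants; everything is reproducible from ``seed``.  When
    ``out_dir`` is given, volumes/masks are written as NIfTI with a
    manifest CSV the command-line pipeline consumes unchanged.
    """
    if n_neoplastic < 1 or n_nonneoplastic < 1:
        raise ValidationError("each group needs at least one subject")
    master = np.random.default_rng(seed)
    n_total = n_neoplastic + n_nonneoplastic
    child_seeds = master.integers(0, 2**31 - 1, size=n_total)
    subjects: list[SyntheticSubject] = []
    rows = []
    for i in range(n_total):
        neo = i < n_neoplastic
        spec = (
            _neoplastic_spec(int(child_seeds[i]), master)
            if neo
            else _nonneoplastic_spec(int(child_seeds[i]), master)
        )
        subj = make_phantom(spec)
        subj.subject_id = f"sub-{i + 1:03d}"
        subjects.append(subj)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": spec.group,
                "truth_population_skewness": subj.truth["population_skewness"],
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        suv_paths, mask_paths, sphere_specs = [], [], []
        for subj in subjects:
            suv_path = out / f"{subj.subject_id}_suv.nii.gz"
            mask_path = out / f"{subj.subject_id}_lesion.nii.gz"
            write_suv_volume(subj.suv_volume, suv_path)
            write_mask(subj.lesion_mask, mask_path)
            suv_paths.append(str(suv_path))
            mask_paths.append(str(mask_path))
            sphere_specs.append(
                json.dumps([[*s.center, s.diameter] for s in subj.reference_spheres])
            )
        manifest["suv_path"] = suv_paths
        manifest["lesion_mask_path"] = mask_paths
        manifest["ref_spheres"] = sphere_specs
        manifest.to_csv(out / "manifest.csv", index=False)
    return subjects, manifest
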