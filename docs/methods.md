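# Methods

## SUV model

The pipeline works on standard-uptake-value maps. Given an activity
concentration volume `C` in Bq/mL and acquisition metadata,

    SUV(v) = C(v) · body_weight[g] / (injected_dose[Bq] · decay_factor),

dimensionless under the 1 g/mL tissue-density convention. The decay factor
is an explicit input in (0, 1] rather than being derived from a half-life:
whether the dose is corrected to injection time or to scan start is a
site-specific convention, and keeping the factor explicit makes the
normalization auditable. Volumes are stored float64 in memory and float32 on
disk (NIfTI); PET dynamic range makes this lossless in practice. All
geometry uses the NIfTI RAS+ world frame; voxel volume is
`|det(A₃ₓ₃)| / 1000` mL from the image affine, valid for anisotropic and
oblique grids.

## ROIs and voxel extraction

The lesion ROI is assumed to be delineated on the anatomical scan and
co-registered with the PET; registration estimation is out of scope. Binary
masks on a foreign grid are resampled to the PET grid by nearest neighbor
through world coordinates (a target voxel is inside iff its world center
maps into a true source voxel); intensity images are never resampled, so
features are always computed on native PET voxels.

A voxel belongs to a spherical ROI iff its **center** lies within the
radius (inclusive). Reference regions are three 1-cm spheres placed at the
lesion centroid reflected across the midsagittal plane (default: the
volume's world-x midplane, overridable), dispersed by 0/±12 mm along the
superior–inferior axis so they do not coincide — the dispersal scheme is a
package convention, since manual placement cannot be reproduced exactly;
explicit world-coordinate sphere specifications are accepted instead.
Nmax/Nmean are computed on the **pooled** voxel set of the three spheres.

The voxel series `X(i)` is read in ascending linear (C-scan) index order —
all downstream statistics are order-invariant, but a fixed order keeps
outputs byte-reproducible.

## Features

* `SUVmax`, `SUVmean`, `SUVmedian` over the ROI series (even-length median =
  midpoint of the two central order statistics).
* `MTV = Np · voxel_volume` (mL); `TLA = SUVmean · MTV` (mL·SUV), which
  equals `Σ X(i) · voxel_volume` exactly — a conservation identity the test
  suite asserts.
* `T/N = SUVmax / Nmax`; a zero reference maximum raises rather than
  returning infinity.
* `skewness` — population (divide-by-Np) third standardized moment, exactly
  as defined, with no Fisher–Pearson small-sample adjustment. Zero-variance
  series yield NaN with a warning, never a silent 0; Np < 2 is rejected.
* `tendency = SUVmean − SUVmedian` (SUV units).
* The display histogram uses 64 uniform bins on the fixed range SUV 0–4
  (out-of-range voxels accumulate in the terminal bins, with a warning, so
  counts always sum to Np). The bin count is a display knob only; skewness
  and tendency are computed from raw voxels, never from binned counts.

## Classification

A feature votes non-neoplastic iff its value is **strictly greater** than
its threshold (exactly-at-threshold votes neoplastic; the tie is
documented, not load-bearing). Default thresholds are the published
cut-offs, skewness 0.624 and tendency 0.084, applied in `skewness_only`
mode: the published case material shows the two features can disagree (a
necrotic core with skewness 1.019 but tendency 0.064), and the clinical
narrative follows skewness. `tendency_only`, `either` and `both` modes are
exposed for sensitivity analysis; both votes are always reported. An
undefined skewness abstains instead of guessing.

The derivation of the published cut-offs is undocumented. Two candidate
derivations are provided: midpoint of the group means, and the empirical
Youden-optimal cut (candidate cuts at observed values, decision rule
`value ≥ cut`, positive class = higher-mean group, ties to the smallest
maximizing cut — with perfectly separated groups this returns the smallest
positive-group value). The midpoint of the published group means is
0.540 (skewness) and 0.062 (tendency), neither of which equals the printed
cut-offs; cohort reports therefore flag the thresholds as external constants
whose derivation is not reproduced, rather than pretending agreement.

## Group comparison

Means and SDs use the sample (n−1) convention matching mean ± SD reporting.
Two tests are reported side by side: the Wilcoxon rank-sum test (exact null
distribution via the Mann–Whitney U statistic for tie-free pooled samples of
≤ 25, otherwise the normal approximation with tie correction) and Welch's
unequal-variance t test — the nonparametric test is the safer default for a
small imbalanced cohort, the parametric one is kept because published group
tables conventionally use it and group variances clearly differ. No
multiple-testing correction is applied, matching the analysis being
reproduced.

## Synthetic phantoms

The generator emulates the statistical structure the analysis depends on,
not PET physics:

| parameter | default | rationale |
|---|---|---|
| grid | 96×96×60 @ 2 mm | ~10³-voxel lesions, seconds-scale generation |
| background | trunc-normal(0.10, 0.01) | normal-brain level giving T/N ≈ 20 |
| lesion radius | 15 mm (cohort: U(10, 20)) | MTV of a few–tens of mL |
| neoplastic law | Gaussian(1.30, 0.35) | SUVmax over ~1700 voxels ≈ 2.5; P(X<0) ≈ 1e-4 |
| non-neoplastic law | gamma, shape 4.57, mean 0.9 | population skewness 2/√4.57 ≈ 0.936 |
| cohort sizes | 18 vs 3 | the modeled study's group sizes |

Lesion voxels are i.i.d. draws clipped at zero. The gamma family was chosen
over alternatives (e.g. skew-normal) because its population skewness
`2/√shape` is closed-form, so every phantom doubles as an exact
parameter-recovery oracle; mixture laws get closed-form skewness through
weighted raw moments. Per-subject cohort heterogeneity is lognormal jitter
on the law parameters (15% on Gaussian μ and σ, 25% on gamma shape, 10% on
the gamma mean). This reproduces the two groups' mean feature values; it
deliberately does **not** reproduce the published non-neoplastic skewness SD
(0.448), which is a 3-subject sample SD and therefore mostly noise —
matching it would push individual non-neoplastic phantoms across the 0.624
cut, a behavior the published per-case data do not show.

What the phantoms do *not* model: spatial voxel correlation, scanner PSF
blur, Poisson counting noise, reconstruction artifacts, anatomy. Passing
tests therefore demonstrate that the feature definitions, thresholds and
statistics behave as specified on data with the assumed distributional
structure — not that the classification accuracy transfers to real
patients.

The ring+core phantom fills an outer shell and an inner core from different
laws (e.g. Gaussian rim, gamma core), producing the dual-peaked whole-lesion
histogram that splits into single peaks on the sub-segmentations. For the
second mode to be detectable the core must hold a sizeable voxel fraction;
the test fixture uses outer 16 mm / inner 13 mm (core ≈ 54% of voxels — a
thin proliferating rim around a large necrotic core).

## Numerical and degenerate-input choices

* Skewness of a zero-variance series: NaN + warning; classification then
  abstains.
* Sphere rasterization boundary: inclusive (`≤ r`); rasterization is exact
  against a per-voxel distance oracle, computed only within a conservative
  index bounding box for speed.
* Mask resampling onto an identical grid returns an exact copy (identity).
* A lesion centroid exactly on the midsagittal plane warns and mirrors to
  itself rather than failing.
* Clipping lesion draws at zero perturbs the truth skewness by far less
  than the recovery tolerance `2·√(6/Np)` (measured bias ≈ 0.003 for the
  default Gaussian law over 200 replicates).
* All cohort/phantom randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived child seeds stay below 2³¹.

## Problem sizes used in checks

Formula oracle: 1000 random series. Recovery: 200 replicate phantoms per
law (~1700 voxels each). Separation: 100 cohort seeds in the test suite, 50
in the acceptance script; balanced accuracy pools 5 cohorts (105 subjects).

## Known limitations

* Cohort-level feature values (group SDs, MTV/TLA distributions, exact
  p-values) from the original patient data are not reproducible without the
  images; the pipeline reproduces the *method* and verifies it on phantoms
  plus the published per-case feature values.
* Registration, segmentation, partial-volume effects and dynamic (4D) PET
  are out of scope; masks and co-registered volumes are inputs.
* TLA units are reported as mL·SUV; the original tables leave the unit
  unstated.
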