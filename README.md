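# suvhist

SUV-histogram quantification of brain PET lesions: traditional metabolic
features, first-order histogram features, and skewness-based differentiation
of neoplastic from non-neoplastic lesions.

## The problem

Amino-acid PET tracers accumulate both in proliferating brain tumors and in
treatment-related changes such as radiation necrosis or encephalitis, so the
usual intensity parameters — SUVmax, SUVmean, metabolic tumor volume (MTV),
total lesion activity (TLA), tumor-to-normal-brain ratio (T/N) — often cannot
tell the two apart. What does differ is the *shape* of the voxel-value
distribution inside the lesion: proliferating tumor uptake is approximately
normally distributed over the ROI, whereas necrotic/inflammatory lesions
pile their voxels up near background with a long right tail — a positively
skewed histogram.

`suvhist` implements that analysis as a reusable pipeline for
neuro-oncology imaging researchers: SUV-map construction from activity
volumes, ROI voxel extraction on the native PET grid, feature computation,
threshold classification, and cohort-level statistics. Because patient
images behind the published cohort are not publicly deposited, the package
ships a synthetic-phantom generator with closed-form ground truth so the
entire pipeline is testable end to end.

## The statistics at the core

For the SUV number series `X(i), i = 1..Np` of voxels inside the lesion ROI:

```
skewness = ( (1/Np) Σᵢ (X(i) − X̄)³ ) / ( sqrt( (1/Np) Σᵢ (X(i) − X̄)² ) )³
tendency = SUVmean − SUVmedian
```

Skewness is the population (divide-by-Np) third standardized moment — no
small-sample correction — and tendency is a cheap one-number surrogate for
right-skew. A lesion votes **non-neoplastic** when a feature exceeds its
cut-off (published values: skewness > 0.624, tendency > 0.084); by default
the skewness vote decides the label, since the two features can disagree.

Traditional parameters are computed alongside: `MTV = Np × voxel volume`,
`TLA = SUVmean × MTV`, `T/N = SUVmax / Nmax`, where Nmax/Nmean come from the
pooled voxels of three 1-cm reference spheres mirrored to the contralateral
hemisphere.

## Worked example

Generate a synthetic non-neoplastic phantom (gamma-law lesion, population
skewness 2/√4.57 ≈ 0.936) and push it through the pipeline:

```python
from suvhist import PhantomSpec, GammaLaw, make_phantom, classify
from suvhist.cli import compute_subject_features

spec = PhantomSpec(law=GammaLaw.from_mean(4.57, 0.9),
                   group="non-neoplastic", seed=42)
subject = make_phantom(spec)
feats, series = compute_subject_features(
    subject.suv_volume, subject.lesion_mask, subject.reference_spheres
)
result = classify(feats)
```

This prints (via the obvious f-strings):

```
Np        = 1736
SUVmax    = 2.856
SUVmean   = 0.883
MTV       = 13.9 mL
TLA       = 12.3 mL*SUV
T/N ratio = 22.8
skewness  = 1.001   (population truth 0.936)
tendency  = 0.054
label     = non-neoplastic   votes = {'skewness': 'non-neoplastic', 'tendency': 'neoplastic'}
```

The 15-mm lesion covers 1736 voxels (13.9 mL) on the 2-mm grid; its SUVmax
and T/N sit in the range typical of amino-acid-avid brain lesions, so the
traditional parameters alone would not flag it. The sample skewness 1.001
estimates the generating law's 0.936 within sampling error and exceeds the
0.624 cut, so the lesion is labelled non-neoplastic — note the discordant
tendency vote, which the default `skewness_only` rule ignores but always
reports.

## Command line

```sh
suvhist simulate --out cohort/ --seed 7            # synthetic cohort + manifest
suvhist cohort --manifest cohort/manifest.csv --out results/
suvhist features --suv sub-001_suv.nii.gz --lesion-mask sub-001_lesion.nii.gz --out sub-001/
suvhist classify --features cases.csv              # bare skewness/tendency CSV
```

`suvhist cohort` writes a per-subject feature table, per-subject
classifications, and a report with group mean ± SD per feature, Wilcoxon
rank-sum and Welch t-test p-values, and candidate threshold derivations
(midpoint-of-means, Youden) — explicitly flagged as not reproducing the
published cut-offs, whose derivation is undocumented.

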