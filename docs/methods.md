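# Methods

## The quantification problem

Amyloid-PET intensity in a region mixes signal from gray matter (where
amyloid plaques accumulate) with white matter and CSF included in the
anatomical region definition. Neurodegeneration shifts that mixture: as
gray matter is lost, the all-voxel regional mean is pulled toward the
non-GM uptake level, which in AD *counteracts* the plaque-driven signal
increase and blurs the group difference. Restricting both the target and
the reference means to voxels that are gray matter in the subject's own
tissue-probability map removes this dilution. `gmsuvr` implements both
quantification modes behind one interface so their statistical behaviour
can be compared like for like.

Conventions: voxel indices are 0-based; world coordinates are mm in the
affine's frame; GM membership is `probability >= threshold` (inclusive),
default threshold 0.5; volumes are stored as float32, labels as unsigned
integers; mismatched grids are an error, never silently resampled. In
GM-masked mode the reference region is masked as well (the measure should
treat all regions alike); `mask_reference=False` reproduces the older
reference-only-masking convention. A region whose GM intersection is empty
yields a missing value and a warning (a hard error under `strict`), and
subjects with missing rows are excluded from classification with a logged
list.

## The phantom cohort

No clinical data ships with the package; every analysis runs on a
synthetic cohort built to exhibit the statistical structure the method
question turns on, not to mimic real anatomy.

**Geometry.** Eleven disjoint boxes on a 3×4×2 cell lattice: ten target
regions (medial/lateral temporal, precuneus, posterior/anterior cingulate,
frontal, occipital, striatum, thalami, parietal) plus a cerebellar
reference. Fill fractions give a wide size distribution (frontal ≈ 18× the
precuneus voxel count on the default grid, mirroring the extreme size ratio
of real parcellations). Default grid 40×48×40 at 3 mm for desk-scale
runtime; a `mni_scale()` preset provides the full normalised-space grid
(121×141×121 at 1.5 mm). Grids too small to host all regions with ≥ 20
voxels raise a sizing error.

**Tissue template.** Within every region — reference included — the
innermost 70% of voxels (by centroid distance, axis-normalised) form a GM
core with probability 1.0; the rim has probability 0.15. Because target
and reference share this composition, the all-voxel SUVR of every region
is exactly 1 under the null, so the two quantification modes start from
the same baseline.

**PET signal.** For a subject with global scale `s` (uniform in
[0.8, 1.25]; cancels in every ratio), a brain voxel with GM probability
`g` in region `r` gets

```
pet = s · [ g · u_r + (1 − g) · u_nongm ] + ε,   ε ~ N(0, 0.05 · s)
```

with `u_r = baseline (1.0) + AD elevation (region-specific, 0.05–0.35)
+ burden + jitter` for target regions and `u_r = 1.0 + jitter` for the
cerebellum (never elevated, never atrophied). `burden ~ N(0, 0.12)` is
shared across a subject's target regions — the dominant between-subject
variability, standing in for the amyloid-positivity continuum that makes
real cohorts overlap — and `jitter ~ N(0, 0.08)` is independent per
subject × region. Without these terms, voxel averaging would shrink
regional noise to nothing and the groups would separate perfectly, which
no clinical cohort does.

**Atrophy.** Each subject loses the outermost fraction `a` of every target
region's GM core to the rim probability level, with
`a ~ N(0.25, 0.10)` in AD and `N(0.10, 0.10)` in non-AD (clipped to
[0, 0.95]); both parameters scale with `atrophy_factor`, so setting it to 0
gives an exact between-group null. Erosion (rather than scaling every
voxel's probability) is the model choice that makes the mechanism clean:
surviving core voxels keep probability 1.0, so the GM-masked SUVR of an
affected region recovers the configured uptake ratio exactly in the
noise-free limit, while the all-voxel mean is diluted by the enlarged rim.
Per-subject variability in `a`, and nonzero non-AD atrophy, prevent the
voxelwise classifier from reading group membership straight off a fixed
eroded shell — a determinism no real cohort offers.

**Demographics** follow the emulated cohort (AD: n=51, 23M/28F, age
63.4 ± 6.3 clipped to 49–74; non-AD: n=43, 28M/15F, 62.9 ± 8.3 clipped to
42–79) and are metadata only; no analysis consumes them.

**What the phantom does not model:** anatomical shape variability and
registration error, scanner point-spread and spatially correlated noise,
site differences, partial-volume correction, or any coupling between
demographics and signal. Passing tests therefore demonstrate the internal
consistency and calibration of the pipeline and the *mechanical* form of
the masking advantage — not its effect size in clinical data.

## Statistics

**Smoothing.** Isotropic Gaussian FWHM in mm, per-axis
`sigma = FWHM / (2√(2 ln 2)) / voxel_size`; boundary mode is nearest-edge
replication inside the brain bounding box, so empty background does not
bleed into the mask edge and constant volumes are preserved exactly.

**Voxelwise test.** Classical pooled-variance two-sample t (Welch by
flag), one-sided in the stated direction (AD > non-AD for PET; both
directions for GM-probability maps). Voxels with zero within-group
variance get t = 0 with a warning.

**Family-wise error.** Default is permutation max-T: group labels are
randomly reassigned `B` times (default 1000), the maximum t over the brain
mask is recorded each time, and the threshold is the k-th largest maximum
with `k = floor(α(B+1))` — the cut-off at which the permutation p-value of
the observed maximum is ≤ α. This is exact under exchangeability and
adapts to the spatial correlation that smoothing introduces. Bonferroni
(`t` quantile at α/n_voxels) is the fast, conservative fallback.
Permutations are vectorised as two matrix products per batch, with batches
sized to bound memory. Random-field-theory inference is deliberately out
of scope, so printed critical values of RFT-based software are not
comparable targets.

**Regional statistics.** Coverage is the percentage of a region's voxels
inside the FWE-significant mask (volumes reported in mm³ and voxels).
One-way two-group ANOVA per region (F with df (1, n−2), equal to the
pooled t² — asserted in the tests); p-values are reported per region
uncorrected, with a clearly separated Bonferroni-across-regions column.
The Fisher discriminant ratio uses sample (n−1) standard deviations; both
group variances zero with equal means gives J = 0, with unequal means a
warning and a missing value.

**Classification.** Linear soft-margin SVM, cost C = 1, no feature
standardisation by default (SUVRs are already ratio-normalised; a z-score
flag exists and uses training-fold statistics only, avoiding leakage).
Stratified 10-fold cross-validation with seeded shuffling; with 94
subjects folds hold 9–10 subjects (a uniform 85/9 train/test split does
not exist for 94 subjects in 10 folds). Metrics pool the held-out
predictions: AD is the positive class, accuracy/sensitivity/specificity in
percent, ROC swept over the unique pooled decision scores (ties grouped),
AUC by the trapezoidal rule — equal to the Mann–Whitney pair-counting
statistic with ties counted ½, asserted in the tests. Weight maps come
from a single refit on all subjects; the sign convention makes positive
weights push toward AD. Voxel feature sets use cerebellum-referenced voxel
intensities inside the brain mask, or inside a consensus GM mask (voxel GM
in ≥ 50% of subjects — the consensus rule fixes feature dimensionality
across subjects; the fraction is configurable).

**Seeding.** One master seed derives a stage seed per pipeline stage via a
keyed hash (kept below 2³¹), so every stage is independently re-runnable
and the end-to-end summary is byte-reproducible.

## Problem sizes used in the shipped analyses

The drivers and the acceptance script run the default 94-subject cohort on
the 40×48×40 grid (≈ 7400 brain voxels), 1000 permutations for the FWE
threshold, 10 cohort replicates for the stability comparison, and 200
noise replicates at 500 permutations each (8×10×8 grid, 8 + 8 subjects)
for the family-wise-error calibration — sizes chosen so the whole chain
reruns from scratch in well under a minute while keeping Monte-Carlo error
small relative to the effects examined.

## Known limitations

* The atlas is synthetic box geometry; region names map conceptually, not
  anatomically, onto their clinical counterparts. A real label volume can
  be supplied through the atlas reader, but no registration is offered.
* The uptake model is piecewise-constant per region; there are no
  within-region gradients, so coverage percentages are sharper than in
  real maps.
* Permutation inference assumes exchangeability under the null; covariate
  adjustment (age, sex) is not implemented.
* With ~7000 correlated voxel features and 94 subjects, the voxelwise
  classifiers operate near their ceiling on the phantom; differences
  between the two voxel feature sets are not interpretable there, while
  the SUVR pair remains well below ceiling and carries the comparison.
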