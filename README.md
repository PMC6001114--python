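# gmsuvr — gray-matter-masked SUVR quantification of amyloid PET

`gmsuvr` quantifies regional amyloid burden from brain PET as standardized
uptake value ratios (SUVR) and asks a specific methodological question: does
restricting the quantification to **gray-matter voxels** — using each
subject's tissue-probability map — separate Alzheimer's-disease (AD) from
non-AD subjects better than the classical all-voxel computation?

The SUVR of region *k* for one subject is

```
SUVR_k = ( Σ_{i∈k} x_i / N_k ) / ( Σ_{j∈ref} x_j / N_r )
```

the mean PET intensity over the region's voxels divided by the mean over a
reference region (the whole cerebellum). In GM-masked mode both means run
only over voxels whose gray-matter probability is ≥ 0.5, so atrophied and
partial-volume tissue no longer dilutes the regional uptake. The package is
aimed at neuroimaging methodologists who want the full evaluation chain —
quantification, voxelwise inference, effect ranking, and classification —
reproducible end to end without access to clinical data.

It provides:

* a **synthetic phantom cohort** (51 AD / 43 non-AD by default) of
  co-registered PET + GM-probability volumes on a toy 10-region atlas with a
  cerebellar reference, with elevated AD uptake, AD-dominant gray-matter
  atrophy, per-subject global intensity scale, between-subject uptake
  variability and voxel noise;
* **SUVR quantification** in all-voxel and GM-masked modes, plus voxelwise
  cerebellum-referenced normalisation;
* **group statistics**: Gaussian smoothing (FWHM in mm), one-sided pooled-
  variance voxelwise t-maps with family-wise error control (permutation
  max-T or Bonferroni), region coverage of the significant map, per-region
  one-way ANOVA, and the Fisher discriminant ratio
  `J_r = (μ₁−μ₂)² / (σ₁²+σ₂²)`;
* **classification**: stratified 10-fold cross-validated linear SVM (C = 1)
  over four feature sets (regional SUVRs / voxel intensities × all / GM),
  with accuracy, sensitivity, specificity, ROC/AUC and signed weight maps.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py     # phantom cohort -> scratch/, results/
python analysis/02_quantify_suvr.py       # SUVR tables, both modes
python analysis/03_group_differences.py   # t-map + FWE, coverage, ANOVA, J_r
python analysis/04_classification.py      # 4 SVM evaluations
```

`02_quantify_suvr.py` prints the per-group median SUVRs; for the strongest
region the gap roughly doubles under masking — e.g. lateral temporal
AD/non-AD medians 1.121/0.929 all-voxel but 1.327/0.964 GM-masked
(separation 0.192 → 0.362), because atrophy pulls the AD all-voxel mean
toward the non-GM uptake while the GM-restricted mean keeps the full
gray-matter signal. `03_group_differences.py` reports the permutation
max-T threshold (t ≥ 2.615 at FWE α = 0.05 on the default cohort), the
share of each region covered by significant voxels (e.g. precuneus 100%,
thalami 0%), and that the Fisher ratio rises under GM masking in 9 of 10
regions. `04_classification.py` prints the cross-validated table:

```
           n_features  accuracy_pct  sensitivity_pct  specificity_pct    auc
suvr_all         10.0        85.106           84.314           86.047  0.919
suvr_gm          10.0        89.362           88.235           90.698  0.964
voxel_all      7362.0        93.617           94.118           93.023  0.992
voxel_gm       4297.0        93.617           96.078           90.698  0.995
```

GM masking improves the SUVR classifier by ~4 accuracy points here;
negative weights (e.g. thalami) mark regions whose pattern pushes subjects
toward the non-AD side of the hyperplane.

The same pipeline is scriptable in one call:

```bash
gmsuvr run-all --seed 0 --out runs/demo        # or per-stage:
gmsuvr simulate --out data/ --seed 0
gmsuvr quantify --data data/ --mode gm --out suvr_gm.tsv
gmsuvr stats --data data/ --fwe permutation --n-perm 1000 --out stats/
gmsuvr classify --data data/ --features suvr-gm --out cls/
```

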