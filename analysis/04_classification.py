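"""Cross-validated SVM evaluation of the four feature sets.

Trains linear soft-margin SVMs (C = 1) under stratified 10-fold
cross-validation on regional SUVRs and cerebellum-referenced voxel
intensities, with and without gray-matter restriction, then prints the
accuracy / sensitivity / specificity / AUC table and the signed region
weights of the two SUVR classifiers.

Run after 01_simulate_cohort.py:  python analysis/04_classification.py
"""

import importlib
from pathlib import Path

import numpy as np
import pandas as pd

import gmsuvr as g
from gmsuvr.pipeline import derive_seed

RESULTS = Path("results")
SEED = 0


def main() -> None:
    quantify = importlib.import_module("02_quantify_suvr")
    subjects, atlas = quantify.load_cohort()

    t_all = g.compute_suvr_table(subjects, atlas, mode=g.ALL_VOXELS)
    t_gm = g.compute_suvr_table(subjects, atlas, mode=g.GM_MASKED)
    consensus = g.build_group_gm_mask(subjects)
    feats = g.build_feature_sets(subjects, atlas, t_all, t_gm, consensus)

    seed = derive_seed(SEED, "classify")
    RESULTS.mkdir(exist_ok=True)
    rows, weights = {}, {}
    for kind, feat in feats.items():
        kept = set(feat.subject_ids)
        labels = [s.group for s in subjects if s.subject_id in kept]
        rep = g.crossval_classify(feat, labels, n_folds=10, C=1.0, seed=seed)
        rep.to_json(RESULTS / f"classification_{kind}.json")
        np.savetxt(RESULTS / f"roc_{kind}.tsv", rep.roc_points,
                   delimiter="\t", header="fpr\ttpr", comments="")
        rows[kind] = {
            "n_features": feat.matrix.shape[1],
            "accuracy_pct": rep.accuracy,
            "sensitivity_pct": rep.sensitivity,
            "specificity_pct": rep.specificity,
            "auc": rep.auc,
        }
        if feat.feature_names is not None:
            weights[kind] = pd.Series(rep.weights, index=feat.feature_names)

    table = pd.DataFrame(rows).T
    print("cross-validated linear SVM (10-fold, C = 1):")
    print(table.round(3).to_string())
    print("\nsigned region weights of the SUVR classifiers "
          "(positive pushes toward AD):")
    wtab = pd.DataFrame(weights)
    print(wtab.round(3).to_string())
    wtab.round(6).to_csv(RESULTS / "weights_suvr.tsv", sep="\t", index_label="region")
    print(f"\nreports written to {RESULTS}/classification_*.json")


if __name__ == "__main__":
    main()
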