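"""Cross-validated linear max-margin (SVM) classification of AD vs non-AD.

Four feature sets mirror the evaluation design: regional SUVRs (classical
or GM-masked) and cerebellum-referenced voxel intensities (whole brain or
consensus GM mask).  The classifier is a linear soft-margin SVM with cost
C = 1, evaluated by stratified K-fold cross-validation; metrics are pooled
over held-out predictions, the ROC is swept over the pooled decision
scores, and the weight map comes from one refit on all subjects.

AD is the positive class throughout: positive decision scores and positive
weights push toward AD.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .suvr import SUVRTable, voxelwise_normalize
from .volume import AtlasParcellation, Volume

__all__ = [
    "SUVR_ALL",
    "SUVR_GM",
    "VOXEL_ALL",
    "VOXEL_GM",
    "FeatureSet",
    "ClassificationReport",
    "build_feature_sets",
    "crossval_classify",
    "roc_and_auc",
    "extract_weight_map",
]

log = logging.getLogger(__name__)

SUVR_ALL = "suvr_all"
SUVR_GM = "suvr_gm"
VOXEL_ALL = "voxel_all"
VOXEL_GM = "voxel_gm"

POSITIVE_CLASS = "AD"


@dataclass
class FeatureSet:
    """A subjects x features matrix plus the meaning of its columns."""

    kind: str
    matrix: np.ndarray
    subject_ids: list[str]
    feature_names: list[str] | None = None  # SUVR kinds
    feature_mask: Volume | None = None  # voxel kinds: column j <-> j-th mask voxel
    excluded_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("matrix must be subjects x features")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class ClassificationReport:
    kind: str
    fold_assignment: dict[str, int]
    decision_scores: pd.Series
    predicted: pd.Series
    accuracy: float  # percent
    sensitivity: float  # percent, AD positive
    specificity: float  # percent
    fold_accuracies: list[float]
    roc_points: np.ndarray  # (FPR, TPR) rows
    auc: float
    weights: np.ndarray
    intercept: float
    n_folds: int
    C: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_folds": self.n_folds,
            "C": self.C,
            "seed": self.seed,
            "fold_accuracies": self.fold_accuracies,
            "fold_assignment": self.fold_assignment,
            "decision_scores": {k: float(v) for k, v in self.decision_scores.items()},
            "predicted": {k: str(v) for k, v in self.predicted.items()},
            "intercept": self.intercept,
            "n_features": int(self.weights.size),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _suvr_features(table: SUVRTable, kind: str) -> FeatureSet:
    complete = table.values.dropna(axis=0)
    excluded = sorted(set(table.values.index) - set(complete.index))
    if excluded:
        log.warning("%s: excluding subjects with missing SUVRs: %s", kind, excluded)
    return FeatureSet(
        kind=kind,
        matrix=complete.to_numpy(dtype=np.float64),
        subject_ids=list(complete.index),
        feature_names=list(complete.columns),
        excluded_subjects=excluded,
    )


def build_feature_sets(
    subjects: Sequence,
    atlas: AtlasParcellation,
    suvr_all: SUVRTable,
    suvr_gm: SUVRTable,
    gm_consensus_mask: Volume,
) -> dict[str, FeatureSet]:
    """Assemble the four feature sets used for classification.

    SUVR kinds take the 10-region tables; voxel kinds take cerebellum-
    referenced intensities within the brain mask (VOXEL_ALL) or within the
    consensus GM mask (VOXEL_GM).
    """
    out = {
        SUVR_ALL: _suvr_features(suvr_all, SUVR_ALL),
        SUVR_GM: _suvr_features(suvr_gm, SUVR_GM),
    }
    ref_mask = atlas.region_mask(atlas.reference_label)
    brain = atlas.brain_mask
    consensus = gm_consensus_mask.data.astype(bool)
    if not consensus.any():
        raise ValueError("consensus GM mask is empty")
    for kind, vox_mask in ((VOXEL_ALL, brain), (VOXEL_GM, brain & consensus)):
        rows = []
        for s in subjects:
            normed = voxelwise_normalize(s.pet, ref_mask)
            rows.append(np.asarray(normed.data)[vox_mask])
        out[kind] = FeatureSet(
            kind=kind,
            matrix=np.stack(rows),
            subject_ids=[s.subject_id for s in subjects],
            feature_mask=atlas.labels.with_data(
                vox_mask.astype(np.uint8), f"{kind} feature mask"
            ),
        )
    return out


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([1 if g == POSITIVE_CLASS else 0 for g in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("need both classes present")
    return y


def roc_and_auc(decision_scores: np.ndarray, labels: Sequence[str]) -> tuple[np.ndarray, float]:
    """ROC over unique decision scores and its trapezoidal area.

    Tied scores collapse onto one ROC vertex; the curve runs from (0, 0) to
    (1, 1).  The trapezoidal area equals the Mann-Whitney statistic with
    ties counted one half.
    """
    y = _as_binary(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(decision_scores, dtype=float), drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


def crossval_classify(
    features: FeatureSet,
    labels: Sequence[str],
    n_folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
    stratified: bool = True,
    standardize: bool = False,
) -> ClassificationReport:
    """Stratified K-fold cross-validation of a linear SVM (cost ``C``).

    Each subject is held out exactly once; pooled held-out decision scores
    give accuracy/sensitivity/specificity and the ROC.  ``standardize``
    z-scores features with training-fold statistics only.  The reported
    weight vector comes from one refit on all subjects.
    """
    X = features.matrix
    y = _as_binary(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels do not match the feature matrix rows")
    if n_folds < 2 or n_folds > len(y):
        raise ValueError("n_folds must lie in [2, n_subjects]")

    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        from sklearn.model_selection import KFold

        splits = KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X)

    scores = np.empty(len(y))
    pred = np.empty(len(y), dtype=int)
    fold_of = np.empty(len(y), dtype=int)
    fold_accuracies = []
    for fold, (train, test) in enumerate(splits, start=1):
        if len(set(y[train].tolist())) < 2:
            raise ValueError(f"fold {fold}: training partition is missing a class")
        Xtr, Xte = X[train], X[test]
        if standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
        clf = SVC(kernel="linear", C=C)
        clf.fit(Xtr, y[train])
        s = clf.decision_function(Xte)
        scores[test] = s
        pred[test] = (s >= 0).astype(int)
        fold_of[test] = fold
        fold_accuracies.append(float((pred[test] == y[test]).mean() * 100.0))

    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    roc_points, auc = roc_and_auc(scores, list(labels))

    full_w, full_b = extract_weight_map(features, labels, C=C, standardize=standardize)[:2]
    ids = features.subject_ids
    return ClassificationReport(
        kind=features.kind,
        fold_assignment={sid: int(f) for sid, f in zip(ids, fold_of)},
        decision_scores=pd.Series(scores, index=ids, name="g(x)"),
        predicted=pd.Series(
            [POSITIVE_CLASS if p else "NONAD" for p in pred], index=ids, name="predicted"
        ),
        accuracy=100.0 * (tp + tn) / len(y),
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        fold_accuracies=fold_accuracies,
        roc_points=roc_points,
        auc=auc,
        weights=full_w,
        intercept=full_b,
        n_folds=n_folds,
        C=C,
        seed=seed,
    )


def extract_weight_map(
    features: FeatureSet,
    labels: Sequence[str],
    C: float = 1.0,
    standardize: bool = False,
) -> tuple[np.ndarray, float, Volume | None]:
    """Weights of one linear SVM trained on all subjects.

    Positive weights push toward AD.  For voxel feature sets the weights
    are also written back into a Volume at their mask coordinates (zero
    elsewhere); for SUVR kinds the Volume slot is None.
    """
    X = features.matrix
    y = _as_binary(labels)
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        X = (X - mu) / sd
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    w = np.asarray(clf.coef_).ravel()
    b = float(clf.intercept_[0])
    weight_vol = None
    if features.feature_mask is not None:
        out = np.zeros(features.feature_mask.shape)
        out[features.feature_mask.data.astype(bool)] = w
        weight_vol = features.feature_mask.with_data(out, f"{features.kind} SVM weight map")
    return w, b, weight_vol
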