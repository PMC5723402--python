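"""Leave-one-out SVM classification from in-fold cluster features.

Every fold holds out one subject.  Inter-group difference clusters are
re-detected on the training subjects only (voxelwise t-test + extent
threshold), and each feature is the mean map value over one cluster's voxels
for one (band, kind) map type; the identical cluster definitions are then
applied to the held-out subject, so the test subject can influence neither
the feature geometry nor the standardization.  A linear-kernel SVM (C = 1 by
default) is trained on features standardized with training-fold statistics.

Decision scores from all folds are pooled into a single ROC.  The patient
group is the positive class throughout; a score >= 0 predicts patient.  A
fold in which no cluster survives carries no evidence: it is recorded as
feature-less with decision score 0 and, by the sign convention, the patient
label.

Reported accuracy is fold-count based; the per-class mean (balanced)
accuracy is reported alongside it because the two differ on unbalanced
cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.svm import SVC

from .stats import CorrectionConfig, extract_clusters, voxelwise_ttest

POSITIVE = "patient"


@dataclass
class SvmConfig:
    C: float = 1.0


@dataclass
class FoldResult:
    subject_id: str
    true_label: str
    predicted_label: str
    decision_score: float
    clusters: list = field(default_factory=list)  # (band, kind, size) triples
    n_features: int = 0


@dataclass
class ClassificationReport:
    folds: list
    accuracy_pct: float
    balanced_accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    auc: float
    feature_description: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "accuracy_pct": self.accuracy_pct,
            "balanced_accuracy_pct": self.balanced_accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "auc": self.auc,
            "feature_description": self.feature_description,
            "folds": [asdict(f) for f in self.folds],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def roc_auc(decision_scores, true_labels) -> float:
    """Rank-based AUC with ties counted one half (patient = positive)."""
    y = np.asarray([1 if lab == POSITIVE else 0 for lab in true_labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present for ROC analysis")
    return float(roc_auc_score(y, np.asarray(decision_scores, float)))


def roc_points(decision_scores, true_labels) -> pd.DataFrame:
    """ROC curve samples (threshold, FPR, TPR) for export."""
    y = np.asarray([1 if lab == POSITIVE else 0 for lab in true_labels])
    fpr, tpr, thr = roc_curve(y, np.asarray(decision_scores, float))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def confusion_metrics(predictions, true_labels) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %), patient = positive class."""
    preds = np.asarray(predictions)
    truth = np.asarray(true_labels)
    if preds.size == 0:
        raise ValueError("no folds")
    pos = truth == POSITIVE
    tp = np.sum(pos & (preds == POSITIVE))
    fn = np.sum(pos & (preds != POSITIVE))
    tn = np.sum(~pos & (preds != POSITIVE))
    fp = np.sum(~pos & (preds == POSITIVE))
    acc = 100.0 * (tp + tn) / preds.size
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return float(acc), float(sens), float(spec)


def fold_features(
    training_maps: dict,
    training_labels,
    test_maps: dict,
    geometry: tuple,
    cfg: CorrectionConfig,
    min_extent: int,
):
    """In-fold features: mean map value over each training-set difference cluster.

    training_maps / test_maps map (band, kind) -> (n_train, V) array / (V,)
    vector.  Clusters are found per map type by a two-sample t-test on the
    training subjects alone.  Returns (X_train, x_test, cluster list of
    (band, kind, size)).
    """
    labels = np.asarray(training_labels)
    pat = labels == POSITIVE
    if pat.sum() < 2 or (~pat).sum() < 2:
        raise ValueError("need at least 2 training subjects per group")
    cols_train, cols_test, described = [], [], []
    for key in sorted(training_maps):
        stack = np.asarray(training_maps[key], float)
        stat = voxelwise_ttest(stack[pat], stack[~pat], geometry=geometry)
        for rec in extract_clusters(stat, cfg, min_extent):
            rows = rec.voxel_rows
            cols_train.append(stack[:, rows].mean(axis=1))
            cols_test.append(float(np.asarray(test_maps[key], float)[rows].mean()))
            described.append((key[0], key[1], rec.size))
    if not cols_train:
        return np.empty((labels.size, 0)), np.empty(0), []
    return np.column_stack(cols_train), np.asarray(cols_test), described


def loocv_classify(
    cohort_maps: dict,
    labels,
    subject_ids=None,
    svm_config: SvmConfig | None = None,
    cfg: CorrectionConfig | None = None,
    min_extent: int = 1,
) -> ClassificationReport:
    """Leave-one-out linear-SVM discrimination with in-fold cluster features.

    cohort_maps maps (band, kind) -> {"maps": (n_subjects, V) array,
    "geometry": (voxel_index, grid_shape, voxel_size_mm)} or a bare array
    with a shared `geometry` entry under the key "geometry".
    """
    svm_config = svm_config or SvmConfig()
    cfg = cfg or CorrectionConfig()
    geometry = cohort_maps.get("geometry")
    maps = {k: np.asarray(v, float) for k, v in cohort_maps.items() if k != "geometry"}
    if geometry is None:
        raise ValueError("cohort_maps must carry a 'geometry' entry")
    labels = np.asarray(labels)
    n = labels.size
    classes = set(labels.tolist())
    if classes != {"patient", "control"}:
        raise ValueError("labels must contain both 'patient' and 'control'")
    if min((labels == c).sum() for c in classes) < 3:
        raise ValueError("need at least 3 subjects per group")
    if subject_ids is None:
        subject_ids = [f"sub{i:03d}" for i in range(n)]

    folds = []
    for i in range(n):
        train_idx = np.setdiff1d(np.arange(n), [i])
        training = {k: v[train_idx] for k, v in maps.items()}
        testing = {k: v[i] for k, v in maps.items()}
        X, x, clusters = fold_features(
            training, labels[train_idx], testing, geometry, cfg, min_extent
        )
        if X.shape[1] == 0:
            score = 0.0
        else:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Xs = (X - mu) / sd
            xs = (x - mu) / sd
            y = (labels[train_idx] == POSITIVE).astype(int)
            clf = SVC(kernel="linear", C=svm_config.C)
            clf.fit(Xs, y)
            score = float(clf.decision_function(xs[None, :])[0])
        pred = POSITIVE if score >= 0 else "control"
        folds.append(
            FoldResult(
                subject_id=subject_ids[i],
                true_label=str(labels[i]),
                predicted_label=pred,
                decision_score=score,
                clusters=clusters,
                n_features=X.shape[1],
            )
        )

    preds = [f.predicted_label for f in folds]
    truth = [f.true_label for f in folds]
    scores = [f.decision_score for f in folds]
    acc, sens, spec = confusion_metrics(preds, truth)
    balanced = 0.5 * (sens + spec)
    return ClassificationReport(
        folds=folds,
        accuracy_pct=acc,
        balanced_accuracy_pct=float(balanced),
        sensitivity_pct=sens,
        specificity_pct=spec,
        auc=roc_auc(scores, truth),
        feature_description=", ".join(
            f"{b}/{k}" for b, k in sorted(maps)
        ),
    )
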