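"""Random-forest diagnostic harness over network features.

Repeated stratified cross-validation (six folds, ten repetitions by
default) of a random forest on per-subject network features, with
within-training-fold random undersampling of the majority class, per-fold
accuracy / F1 / PPV / NPV / sensitivity / specificity aggregated as
mean +/- sd, a pooled out-of-fold ROC curve with its Youden-optimal
operating point, and a mean-decrease-impurity feature-importance ranking.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from ._utils import derive_seed, rng_for
from .exceptions import InvalidArgumentError


@dataclass(frozen=True)
class ClassificationReport:
    metrics: dict  # name -> (mean, sd)
    auroc_mean: float
    auroc_sd: float
    roc_points: np.ndarray  # (n_points, 2) as (FPR, TPR), pooled out-of-fold
    optimal_point: tuple  # (sensitivity, specificity)
    importance: list  # [(feature, mean importance)] ranked descending
    folds: int
    repeats: int
    positive_class: object

    def summary(self) -> pd.DataFrame:
        rows = [{"metric": k, "mean": m, "sd": s} for k, (m, s) in self.metrics.items()]
        rows.append({"metric": "auroc", "mean": self.auroc_mean, "sd": self.auroc_sd})
        return pd.DataFrame(rows)


def optimal_roc_point(roc_points) -> tuple[float, float]:
    """Youden-optimal ROC point: argmax of TPR - FPR, ties broken toward
    higher specificity. Returns (sensitivity, specificity)."""
    pts = np.asarray(roc_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("need at least 2 (FPR, TPR) points")
    youden = pts[:, 1] - pts[:, 0]
    # lexsort: among maximal Youden values prefer the lowest FPR
    order = np.lexsort((pts[:, 0], -youden))
    fpr, tpr = pts[order[0]]
    return float(tpr), float(1.0 - fpr)


def _undersample(X, y, rng):
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    return X[keep], y[keep]


def rf_crossval(
    features,
    labels,
    folds: int = 6,
    repeats: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    imbalance: str = "undersample",
) -> ClassificationReport:
    """Repeated stratified cross-validation of a random forest.

    `features` is a (subjects x features) DataFrame (column names feed the
    importance ranking) or array. Class imbalance is handled by random
    undersampling of the majority class within each training fold
    (imbalance="undersample", default) or by balanced class weights
    (imbalance="class_weight"). The second of the two sorted class labels
    is treated as the positive class for F1/PPV/NPV/ROC.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise InvalidArgumentError("need at least two classes")
    if len(classes) != 2:
        raise InvalidArgumentError("binary classification only")
    if imbalance not in ("undersample", "class_weight"):
        raise InvalidArgumentError(f"unknown imbalance strategy {imbalance!r}")
    for c in classes:
        if (y == c).sum() < folds:
            raise InvalidArgumentError(f"class {c!r} has fewer subjects than folds={folds}")
    pos = classes[1]
    y_bin = (y == pos).astype(int)
    fold_metrics = {k: [] for k in ("accuracy", "f1", "ppv", "npv",
                                    "sensitivity", "specificity")}
    aurocs = []
    importances = np.zeros(X.shape[1])
    pooled_true, pooled_score = [], []
    n_fits = 0
    us_rng = rng_for(seed, "undersample")
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=derive_seed(seed, "fold", rep))
        for tr, te in skf.split(X, y_bin):
            Xtr, ytr = X[tr], y_bin[tr]
            if imbalance == "undersample":
                Xtr, ytr = _undersample(Xtr, ytr, us_rng)
            clf = RandomForestClassifier(
                n_estimators=n_estimators,
                random_state=derive_seed(seed, "forest", rep, n_fits),
                class_weight="balanced" if imbalance == "class_weight" else None,
            )
            clf.fit(Xtr, ytr)
            score = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
            pred = (score >= 0.5).astype(int)
            yt = y_bin[te]
            tp = int(np.sum((pred == 1) & (yt == 1)))
            tn = int(np.sum((pred == 0) & (yt == 0)))
            fp = int(np.sum((pred == 1) & (yt == 0)))
            fn = int(np.sum((pred == 0) & (yt == 1)))
            fold_metrics["accuracy"].append((tp + tn) / len(yt))
            fold_metrics["f1"].append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
            fold_metrics["ppv"].append(tp / (tp + fp) if (tp + fp) else 0.0)
            fold_metrics["npv"].append(tn / (tn + fn) if (tn + fn) else 0.0)
            fold_metrics["sensitivity"].append(tp / (tp + fn) if (tp + fn) else 0.0)
            fold_metrics["specificity"].append(tn / (tn + fp) if (tn + fp) else 0.0)
            aurocs.append(roc_auc_score(yt, score))
            importances += clf.feature_importances_
            pooled_true.append(yt)
            pooled_score.append(score)
            n_fits += 1
    importances /= n_fits
    fpr, tpr, _ = roc_curve(np.concatenate(pooled_true), np.concatenate(pooled_score))
    roc_points = np.column_stack([fpr, tpr])
    ranking = sorted(zip(names, importances), key=lambda kv: -kv[1])
    return ClassificationReport(
        metrics={k: (float(np.mean(v)), float(np.std(v))) for k, v in fold_metrics.items()},
        auroc_mean=float(np.mean(aurocs)), auroc_sd=float(np.std(aurocs)),
        roc_points=roc_points,
        optimal_point=optimal_roc_point(roc_points),
        importance=[(n, float(v)) for n, v in ranking],
        folds=folds, repeats=repeats, positive_class=pos,
    )
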