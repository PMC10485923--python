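"""Model evaluation: stratified cross-validation, confusion matrix,
calibration with Brier scores, and ROC/AUC.

The headline metrics are computed on predictions pooled across the K
held-out folds (each sample predicted exactly once); per-fold metrics are
retained alongside for dispersion. The calibration curve follows a
random-partition scheme: samples are shuffled into equal-size bins and
each bin contributes (mean predicted probability, fraction of positives).
The Brier skill score is measured against the constant climatology
forecaster p0 = mean(y), whose Brier score is p0 (1 - p0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from hdx2ss._errors import ValidationError
from hdx2ss.gb_core import FeatureTable, GBConfig, fit, predict_proba

logger = logging.getLogger(__name__)


def stratified_kfold(y: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Assign each sample a fold index 0..k-1, stratified by class.

    Within each class, shuffled indices are dealt round-robin, so every
    fold's class proportion is within one sample of the global proportion.
    """
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    fold_of = np.full(len(y), -1, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValidationError(f"class {cls} has {len(idx)} members, fewer than K={k}")
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    return fold_of


def confusion(y: Sequence[int], p: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Row-normalized 2x2 confusion matrix.

    Rows are true classes (0, 1), columns predicted classes; each row
    sums to 1, so the diagonal holds the true-negative and true-positive
    rates.
    """
    y = np.asarray(y, dtype=int)
    pred = (np.asarray(p, dtype=float) >= threshold).astype(int)
    if len(y) != len(pred):
        raise ValidationError("y and p differ in length")
    mat = np.zeros((2, 2))
    for t in (0, 1):
        mask = y == t
        n = mask.sum()
        if n == 0:
            continue
        mat[t, 0] = (pred[mask] == 0).sum() / n
        mat[t, 1] = (pred[mask] == 1).sum() / n
    return mat


def brier_score(y: Sequence[int], p: Sequence[float]) -> float:
    """Mean squared error of probabilistic forecasts."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    return float(((p - y) ** 2).mean())


def calibration(
    y: Sequence[int],
    p: Sequence[float],
    n_bins: int = 20,
    seed: int = 0,
) -> Tuple[List[Tuple[float, float, int]], float, float]:
    """Random-partition calibration curve with Brier and Brier-skill scores.

    Samples are shuffled (seeded) and split into ``n_bins`` near-equal
    groups; each group yields (mean predicted p, fraction positive,
    count). Returns (bins, brier, brier_skill) where brier_skill is
    1 - BS / BS_ref against the constant p0 = mean(y) forecaster.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(y)
    if n < n_bins:
        logger.warning("calibration: n=%d < n_bins=%d; using %d bins", n, n_bins, n)
        n_bins = n
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    groups = np.array_split(order, n_bins)
    bins = [(float(p[g].mean()), float(y[g].mean()), int(len(g))) for g in groups]
    bs = brier_score(y, p)
    p0 = float(y.mean())
    bs_ref = p0 * (1.0 - p0)  # Brier of the constant climatology forecaster
    skill = 1.0 - bs / bs_ref if bs_ref > 0 else 0.0
    return bins, bs, skill


def roc_auc(y: Sequence[int], p: Sequence[float]) -> Tuple[List[Tuple[float, float, float]], float]:
    """ROC curve by threshold sweep over unique scores, with trapezoidal AUC.

    Tied scores share a threshold (a diagonal ROC segment). Returns
    (points, auc) with points as (FPR, TPR, threshold) from (0,0) to
    (1,1).
    """
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: both classes must be present")
    order = np.argsort(-p, kind="mergesort")
    ps = p[order]
    ys = y[order]
    points = [(0.0, 0.0, float("inf"))]
    tp = fp = 0
    i = 0
    n = len(y)
    while i < n:
        thr = ps[i]
        while i < n and ps[i] == thr:
            if ys[i] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos, float(thr)))
    fpr = np.array([pt[0] for pt in points])
    tpr = np.array([pt[1] for pt in points])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


@dataclass
class ValidationReport:
    """Pooled cross-validation metrics plus per-fold dispersion."""

    confusion: np.ndarray
    calibration_bins: List[Tuple[float, float, int]]
    brier: float
    brier_skill: float
    roc: List[Tuple[float, float, float]]
    auc: float
    per_fold: List[Dict[str, float]] = field(default_factory=list)
    feature_importance: Optional[np.ndarray] = None
    pooled_p: Optional[np.ndarray] = None
    pooled_y: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "calibration_bins": [list(b) for b in self.calibration_bins],
            "brier": self.brier,
            "brier_skill": self.brier_skill,
            "roc": [list(pt) for pt in self.roc],
            "auc": self.auc,
            "per_fold": self.per_fold,
            "feature_importance": (
                None if self.feature_importance is None else list(map(float, self.feature_importance))
            ),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def cross_validate(
    table: FeatureTable,
    cfg: GBConfig,
    k: int = 5,
    seed: int = 0,
    n_bins: int = 20,
) -> ValidationReport:
    """Stratified K-fold cross-validation of the boosting model.

    Trains on K-1 folds and predicts the held-out fold, K times; every
    sample is predicted exactly once. Pooled held-out predictions feed
    the confusion matrix, calibration curve and ROC; per-fold AUC/Brier
    are kept for dispersion. Mean per-fold feature importance is attached.
    """
    from hdx2ss.gb_core import feature_importance as _fi

    fold_of = stratified_kfold(table.y, k, seed)
    pooled_p = np.empty(len(table))
    per_fold = []
    importances = []
    for f in range(k):
        tr, va = fold_of != f, fold_of == f
        sub = FeatureTable(table.X[tr], table.y[tr], table.feature_names)
        model = fit(sub, cfg)
        p_va = predict_proba(model, table.X[va])
        pooled_p[va] = p_va
        importances.append(_fi(model))
        fold_metrics = {"fold": f, "n": int(va.sum()), "brier": brier_score(table.y[va], p_va)}
        try:
            _, fold_auc = roc_auc(table.y[va], p_va)
            fold_metrics["auc"] = fold_auc
        except ValidationError:
            fold_metrics["auc"] = float("nan")
        per_fold.append(fold_metrics)

    bins, bs, skill = calibration(table.y, pooled_p, n_bins=n_bins, seed=seed)
    points, auc = roc_auc(table.y, pooled_p)
    return ValidationReport(
        confusion=confusion(table.y, pooled_p),
        calibration_bins=bins,
        brier=bs,
        brier_skill=skill,
        roc=points,
        auc=auc,
        per_fold=per_fold,
        feature_importance=np.mean(importances, axis=0),
        pooled_p=pooled_p,
        pooled_y=np.asarray(table.y),
    )
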