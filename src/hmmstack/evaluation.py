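"""Confusion-matrix metrics, ROC/AUC and cross-validation drivers.

Metrics over the 2x2 confusion table (positive class = DNA-binding
protein = 1):

* overall accuracy   OA  = (TP + TN) / (TP + FP + TN + FN)
* sensitivity        SN  = TP / (TP + FN)
* specificity        SP  = TN / (TN + FP)
* Matthews coeff.    MCC = (TP*TN - FP*FN) /
                           sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 when any denominator factor is 0; SN/SP with an empty
denominator are reported as NaN, never silently 0.  AUC is the trapezoidal
area under the ROC curve, equal to the tie-corrected Mann-Whitney statistic
normalized by n_pos * n_neg.

Evaluation protocols: the jackknife (leave-one-out — every protein scored
by a stack trained on all the others), its stratified k-fold surrogate, and
a single-pass independent test of an already-trained model.  Cross-validated
metrics are computed once over the pooled out-of-fold predictions, giving a
single ROC curve.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
from sklearn.metrics import roc_curve

from .features import FeatureMatrix, batch_encode
from .hhm_io import LabeledDataset
from .stacking import StackConfig, StackedModel, predict_proba, train_stacked

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_counts",
    "compute_metrics",
    "mcc_sqrt",
    "mcc_linear",
    "roc_auc",
    "jackknife_evaluate",
    "kfold_evaluate",
    "independent_test",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvaluationReport:
    """Pooled evaluation result: counts, headline metrics, ROC, per-sample scores."""

    counts: ConfusionCounts
    oa: float
    sn: float
    sp: float
    mcc: float
    auc: Optional[float] = None
    roc: Optional[list[tuple[float, float]]] = None
    per_sample: list[tuple[str, int, float, int]] = field(default_factory=list)
    protocol: str = "independent"

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "counts": {
                "TP": self.counts.TP,
                "FP": self.counts.FP,
                "TN": self.counts.TN,
                "FN": self.counts.FN,
            },
            "OA_pct": round(100.0 * self.oa, 2),
            "SN_pct": None if math.isnan(self.sn) else round(100.0 * self.sn, 2),
            "SP_pct": None if math.isnan(self.sp) else round(100.0 * self.sp, 2),
            "MCC": round(self.mcc, 4),
            "AUC": None if self.auc is None else round(self.auc, 4),
            "roc": self.roc,
            "per_sample": [
                {"id": i, "label": int(t), "score": float(s), "predicted": int(p)}
                for i, t, s, p in self.per_sample
            ],
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        parts = [f"protocol={self.protocol}", f"OA={100 * self.oa:.2f}%"]
        if not math.isnan(self.sn):
            parts.append(f"SN={100 * self.sn:.2f}%")
        if not math.isnan(self.sp):
            parts.append(f"SP={100 * self.sp:.2f}%")
        parts.append(f"MCC={self.mcc:.4f}")
        if self.auc is not None:
            parts.append(f"AUC={self.auc:.4f}")
        return "  ".join(parts)


def _check_binary(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 labels")
    return y.astype(np.int64)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally the 2x2 confusion table (positive = 1)."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def mcc_sqrt(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient with the square-root denominator.

    Defined as 0 when any of the four denominator factors is 0 (the
    standard convention for degenerate tables).
    """
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def mcc_linear(c: ConfusionCounts) -> float:
    """MCC variant without the square root (non-standard; for comparison)."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / denom


def roc_auc(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC from continuous scores.

    The curve is a threshold sweep over the distinct scores (ties grouped);
    it starts at (0, 0) and ends at (1, 1).  The trapezoidal area equals the
    Mann-Whitney probability that a positive outscores a negative, ties
    counted 1/2.
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.sum() == 0 or y_true.sum() == len(y_true):
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return [(float(f), float(t)) for f, t in zip(fpr, tpr)], auc


def compute_metrics(
    counts: ConfusionCounts,
    scores: Optional[tuple[np.ndarray, np.ndarray]] = None,
    protocol: str = "independent",
    per_sample: Optional[list[tuple[str, int, float, int]]] = None,
    use_sqrt_mcc: bool = True,
) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from confusion counts.

    ``scores`` is an optional ``(y_true, score_vector)`` pair used for
    ROC/AUC.  SN (resp. SP) is NaN when no true positives+false negatives
    (resp. negatives) exist.
    """
    if counts.n == 0:
        raise ValueError("cannot compute metrics on zero samples")
    oa = (counts.TP + counts.TN) / counts.n
    sn = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else float("nan")
    sp = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else float("nan")
    mcc = mcc_sqrt(counts) if use_sqrt_mcc else mcc_linear(counts)
    roc_pts, auc = (None, None)
    if scores is not None:
        roc_pts, auc = roc_auc(scores[0], scores[1])
    return EvaluationReport(
        counts=counts,
        oa=oa,
        sn=sn,
        sp=sp,
        mcc=mcc,
        auc=auc,
        roc=roc_pts,
        per_sample=per_sample or [],
        protocol=protocol,
    )


def _as_feature_matrix(data: Union[LabeledDataset, FeatureMatrix]) -> FeatureMatrix:
    if isinstance(data, FeatureMatrix):
        return data
    return batch_encode(data)


def _subset(fm: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        ids=[fm.ids[i] for i in idx],
        X=fm.X[idx],
        y=None if fm.y is None else fm.y[idx],
        names=list(fm.names),
    )


def _cv_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    n = len(y)
    if k == n:  # leave-one-out: the jackknife
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(n), y))


def kfold_evaluate(
    config: StackConfig,
    data: Union[LabeledDataset, FeatureMatrix],
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Pooled out-of-fold evaluation of a stack under stratified k-fold CV.

    For each fold a full stacked model (meta-feature folds re-drawn from the
    config seed) is trained on the remaining folds and scores the held-out
    proteins; metrics are computed once over the pooled predictions.  With
    ``k`` equal to the sample count this is exactly the jackknife.
    """
    fm = _as_feature_matrix(data)
    if fm.y is None:
        raise ValueError("evaluation requires labels")
    y = fm.y
    n = len(fm)
    if k < 2 or k > n:
        raise ValueError(f"k must lie in [2, n={n}], got {k}")
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("each class needs >= 2 members for cross-validation")

    scores = np.empty(n, dtype=np.float64)
    for tr, te in _cv_folds(y, k, seed):
        try:
            model = train_stacked(config, _subset(fm, tr))
        except Exception as exc:
            held = [fm.ids[i] for i in te]
            raise RuntimeError(
                f"training failed with held-out id(s) {held}: {exc}"
            ) from exc
        scores[te] = predict_proba(model, _subset(fm, te))

    y_pred = (scores >= threshold).astype(np.int64)
    counts = confusion_counts(y, y_pred)
    per_sample = [
        (fm.ids[i], int(y[i]), float(scores[i]), int(y_pred[i])) for i in range(n)
    ]
    protocol = "jackknife" if k == n else f"kfold(k={k}, seed={seed})"
    return compute_metrics(
        counts, scores=(y, scores), protocol=protocol, per_sample=per_sample
    )


def jackknife_evaluate(
    config: StackConfig,
    data: Union[LabeledDataset, FeatureMatrix],
    threshold: float = 0.5,
) -> EvaluationReport:
    """Leave-one-out evaluation: every protein scored by a stack trained
    on all the others; metrics over the pooled n predictions."""
    fm = _as_feature_matrix(data)
    if fm.y is None:
        raise ValueError("evaluation requires labels")
    if len(fm) < 3:
        raise ValueError("jackknife requires n >= 3")
    return kfold_evaluate(config, fm, k=len(fm), seed=config.seed, threshold=threshold)


def independent_test(
    model: StackedModel,
    data: Union[LabeledDataset, FeatureMatrix],
    threshold: float = 0.5,
) -> EvaluationReport:
    """Score an already-trained stack on a held-out labeled dataset.

    Warns if any test id also appears in the model's training fingerprint
    (the test would then not be independent).
    """
    fm = _as_feature_matrix(data)
    if fm.y is None:
        raise ValueError("independent test requires labels")
    if len(fm) == 0:
        raise ValueError("test set is empty")
    train_ids = set(model.training_fingerprint.get("training_ids", []))
    overlap = sorted(train_ids.intersection(fm.ids))
    if overlap:
        warnings.warn(
            f"{len(overlap)} test id(s) overlap the training set "
            f"(e.g. {overlap[:5]}); the test is not independent",
            UserWarning,
            stacklevel=2,
        )
    scores = predict_proba(model, fm)
    y_pred = (scores >= threshold).astype(np.int64)
    counts = confusion_counts(fm.y, y_pred)
    per_sample = [
        (fm.ids[i], int(fm.y[i]), float(scores[i]), int(y_pred[i]))
        for i in range(len(fm))
    ]
    return compute_metrics(
        counts, scores=(fm.y, scores), protocol="independent", per_sample=per_sample
    )
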