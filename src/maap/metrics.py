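"""Imbalance-aware multi-class evaluation.

All metrics derive from one-vs-rest confusion counts per class: recall
TP/(TP+FN), precision TP/(TP+FP), F1 = 2PR/(P+R), specificity TN/(TN+FP) and
false-positive rate FP/(FP+TN), macro-averaged as the unweighted mean over
classes so minority classes weigh equally. One-vs-rest AUC is the
rank-statistic (Mann-Whitney) form per class, macro-averaged. Empty cells
(0/0) are defined as 0 with a warning, so reports stay deterministic on
degenerate splits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class."""

    n_classes: int
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn

    @property
    def n_samples(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])


def confusion(y_true, y_pred, n_classes: int = 3) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    if y_true.size == 0:
        raise ValueError("empty label arrays")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.min() < 0 or y.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=int)
    fp = np.zeros(n_classes, dtype=int)
    fn = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        tp[c] = int(np.sum((y_true == c) & (y_pred == c)))
        fp[c] = int(np.sum((y_true != c) & (y_pred == c)))
        fn[c] = int(np.sum((y_true == c) & (y_pred != c)))
    tn = y_true.size - tp - fp - fn
    return ConfusionCounts(n_classes=n_classes, tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(den, dtype=float)
    nz = den != 0
    out[nz] = np.asarray(num, dtype=float)[nz] / den[nz]
    if not nz.all():
        warnings.warn(f"{what}: 0/0 cell(s) reported as 0", RuntimeWarning,
                      stacklevel=3)
    return out


def ovr_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """Per-class one-vs-rest AUC via the Mann-Whitney rank statistic, and its
    unweighted macro mean over classes present in y_true."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y_true.size:
        raise ValueError("scores must be (n_samples, n_classes) aligned with y_true")
    n_classes = scores.shape[1]
    aucs = np.full(n_classes, np.nan)
    for c in range(n_classes):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        ranks = rankdata(scores[:, c])
        aucs[c] = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    present = ~np.isnan(aucs)
    macro = float(aucs[present].mean()) if present.any() else float("nan")
    return aucs, macro


@dataclass
class EvaluationReport:
    """Per-class and macro-averaged classification metrics."""

    n_classes: int
    recall: list[float]
    precision: list[float]
    f1: list[float]
    specificity: list[float]
    fpr: list[float]
    support: list[int]
    macro_recall: float
    macro_precision: float
    macro_f1: float
    macro_specificity: float
    auc_per_class: list[float] | None = None
    macro_auc: float | None = None
    class_names: list[str] = field(
        default_factory=lambda: ["antagonist", "agonist", "modulator"])

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=1), encoding="utf-8")


def macro_report(counts: ConfusionCounts, scores=None, y_true=None) -> EvaluationReport:
    """Build the full report from confusion counts and (optionally) class scores.

    AUC needs *scores* (rows summing to 1 within 1e-6) together with *y_true*.
    """
    recall = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    precision = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    specificity = _safe_div(counts.tn, counts.tn + counts.fp, "specificity")
    fpr = _safe_div(counts.fp, counts.fp + counts.tn, "FPR")

    auc_pc = macro_auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("AUC needs y_true alongside scores")
        scores = np.asarray(scores, dtype=float)
        if scores.shape[0] != counts.n_samples:
            raise ValueError(
                f"scores have {scores.shape[0]} rows for {counts.n_samples} samples"
            )
        if np.abs(scores.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("score rows must sum to 1 within 1e-6")
        per_class, macro_auc = ovr_auc(y_true, scores)
        auc_pc = [float(a) for a in per_class]

    return EvaluationReport(
        n_classes=counts.n_classes,
        recall=recall.tolist(),
        precision=precision.tolist(),
        f1=f1.tolist(),
        specificity=specificity.tolist(),
        fpr=fpr.tolist(),
        support=counts.support.tolist(),
        macro_recall=float(recall.mean()),
        macro_precision=float(precision.mean()),
        macro_f1=float(f1.mean()),
        macro_specificity=float(specificity.mean()),
        auc_per_class=auc_pc,
        macro_auc=macro_auc,
    )


def evaluate(y_true, y_pred, scores=None, n_classes: int = 3) -> EvaluationReport:
    """One-call evaluation: confusion counts then the macro report."""
    return macro_report(confusion(y_true, y_pred, n_classes), scores=scores,
                        y_true=y_true)


def macro_f1(y_true, y_pred, n_classes: int = 3) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return evaluate(y_true, y_pred, n_classes=n_classes).macro_f1
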