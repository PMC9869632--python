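"""Diagnostic-performance evaluation: confusion matrices, proportions with
exact Clopper-Pearson intervals, and one-vs-rest ROC/AUC.

Hard-label metrics (accuracy, sensitivity, specificity, PPV, NPV) are
binomial proportions and get exact 95% intervals from beta quantiles. AUC
is the Mann-Whitney concordance probability (ties half-credit), reported
per class one-vs-rest; the "overall" AUC is the macro average (micro is
also provided), with optional stratified-bootstrap intervals since an exact
interval does not exist for AUC. Slide-level reports additionally cover the
two derived binary tasks: muscle invasion (HGMI vs rest, scored by
``mibc_score``) and grade (HGMI or HGNMI vs LGNMI, scored by
``high_grade_score``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .aggregate import WSIConfidence
from .labels import ALL_CLASSES, DIAGNOSTIC_CLASSES, LabelClass
from .classifier import PatchPrediction

__all__ = [
    "MetricWithCI",
    "EvalReport",
    "clopper_pearson",
    "metric_with_ci",
    "roc_auc",
    "auc_bootstrap_ci",
    "evaluate_wsi",
    "evaluate_patches",
]


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (1-alpha) interval for k successes in n trials."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.isf(alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    lower: float
    upper: float
    k: int
    n: int

    def __str__(self) -> str:
        return f"{self.estimate:.3f} ({self.lower:.3f}-{self.upper:.3f})"


def metric_with_ci(k: int, n: int, alpha: float = 0.05) -> MetricWithCI:
    lower, upper = clopper_pearson(k, n, alpha)
    return MetricWithCI(estimate=k / n, lower=lower, upper=upper, k=k, n=n)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC with half-credit for ties."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both label values must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_bootstrap_ci(scores: Sequence[float], labels: Sequence[int],
                     n_boot: int = 2000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Percentile interval from a class-stratified bootstrap."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        vals[b] = roc_auc_score(labels[idx], scores[idx])
    return (float(np.quantile(vals, alpha / 2)),
            float(np.quantile(vals, 1 - alpha / 2)))


@dataclass
class EvalReport:
    classes: tuple[LabelClass, ...]
    confusion: np.ndarray                       # rows = truth, cols = prediction
    per_class: dict[LabelClass, dict[str, Optional[MetricWithCI]]]
    auc: dict[LabelClass, float]
    macro_auc: float
    micro_auc: float
    overall_accuracy: MetricWithCI
    binary: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def m(v):
            return None if v is None else {
                "estimate": v.estimate, "lower": v.lower, "upper": v.upper,
                "k": v.k, "n": v.n}
        return {
            "classes": [c.name for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": {c.name: {name: m(v) for name, v in d.items()}
                          for c, d in self.per_class.items()},
            "auc": {c.name: self.auc[c] for c in self.classes},
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "overall_accuracy": m(self.overall_accuracy),
            "binary": self.binary,
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def roc_points(self, scores: np.ndarray, truth_idx: np.ndarray,
                   cls: LabelClass) -> np.ndarray:
        """(fpr, tpr, threshold) rows for one one-vs-rest curve."""
        j = self.classes.index(cls)
        fpr, tpr, thr = roc_curve(truth_idx == j, scores[:, j])
        return np.column_stack([fpr, tpr, thr])


def _report(scores: np.ndarray, truth_idx: np.ndarray,
            classes: tuple[LabelClass, ...]) -> EvalReport:
    n = len(truth_idx)
    k = len(classes)
    pred_idx = scores.argmax(axis=1)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (truth_idx, pred_idx), 1)

    per_class: dict[LabelClass, dict[str, Optional[MetricWithCI]]] = {}
    aucs: dict[LabelClass, float] = {}
    for j, cls in enumerate(classes):
        tp = int(confusion[j, j])
        fn = int(confusion[j].sum() - tp)
        fp = int(confusion[:, j].sum() - tp)
        tn = n - tp - fn - fp

        def safe(kk, nn):
            return metric_with_ci(kk, nn) if nn > 0 else None

        per_class[cls] = {
            "sensitivity": safe(tp, tp + fn),
            "specificity": safe(tn, tn + fp),
            "ppv": safe(tp, tp + fp),
            "npv": safe(tn, tn + fn),
            "accuracy": metric_with_ci(tp + tn, n),
        }
        binary_truth = (truth_idx == j).astype(int)
        aucs[cls] = (roc_auc(scores[:, j], binary_truth)
                     if 0 < binary_truth.sum() < n else float("nan"))

    valid = [v for v in aucs.values() if not np.isnan(v)]
    macro = float(np.mean(valid)) if valid else float("nan")
    onehot = np.zeros_like(scores)
    onehot[np.arange(n), truth_idx] = 1.0
    try:
        micro = roc_auc(scores.ravel(), onehot.ravel().astype(int))
    except ValueError:
        micro = float("nan")
    return EvalReport(
        classes=classes,
        confusion=confusion,
        per_class=per_class,
        auc=aucs,
        macro_auc=macro,
        micro_auc=micro,
        overall_accuracy=metric_with_ci(int((pred_idx == truth_idx).sum()), n),
    )


def _binary_block(score: np.ndarray, pred_pos: np.ndarray,
                  truth_pos: np.ndarray) -> dict:
    n = len(truth_pos)
    tp = int((pred_pos & truth_pos).sum())
    tn = int((~pred_pos & ~truth_pos).sum())
    fp = int((pred_pos & ~truth_pos).sum())
    fn = n - tp - tn - fp
    block = {
        "auc": (roc_auc(score, truth_pos.astype(int))
                if 0 < truth_pos.sum() < n else float("nan")),
        "accuracy": metric_with_ci(tp + tn, n),
        "sensitivity": metric_with_ci(tp, tp + fn) if tp + fn else None,
        "specificity": metric_with_ci(tn, tn + fp) if tn + fp else None,
        "ppv": metric_with_ci(tp, tp + fp) if tp + fp else None,
        "npv": metric_with_ci(tn, tn + fn) if tn + fn else None,
    }
    return {kk: ({"estimate": v.estimate, "lower": v.lower, "upper": v.upper,
                  "k": v.k, "n": v.n} if isinstance(v, MetricWithCI) else v)
            for kk, v in block.items()}


def evaluate_wsi(preds: Sequence[WSIConfidence],
                 truth: Sequence[LabelClass]) -> EvalReport:
    """Three-way slide-level report plus the two derived binary tasks."""
    if len(preds) != len(truth):
        raise ValueError(f"length mismatch: {len(preds)} vs {len(truth)}")
    classes = DIAGNOSTIC_CLASSES
    scores = np.array([[p.prob[c] for c in classes] for p in preds])
    idx = {c: j for j, c in enumerate(classes)}
    truth_idx = np.array([idx[t] for t in truth])
    if len(set(truth_idx.tolist())) < 2:
        raise ValueError("need at least two classes in the truth labels")
    report = _report(scores, truth_idx, classes)

    mibc_truth = np.array([t == LabelClass.HGMI for t in truth])
    mibc_pred = np.array([p.predicted_label == LabelClass.HGMI for p in preds])
    hg_truth = np.array([t in (LabelClass.HGMI, LabelClass.HGNMI) for t in truth])
    hg_pred = np.array([p.predicted_label in (LabelClass.HGMI, LabelClass.HGNMI)
                        for p in preds])
    report.binary = {
        "muscle_invasion": _binary_block(
            np.array([p.mibc_score for p in preds]), mibc_pred, mibc_truth),
        "high_grade": _binary_block(
            np.array([p.high_grade_score for p in preds]), hg_pred, hg_truth),
    }
    return report


def evaluate_patches(preds: Sequence[PatchPrediction],
                     truth: Sequence[LabelClass]) -> EvalReport:
    """Six-class patch-level report."""
    if len(preds) != len(truth):
        raise ValueError(f"length mismatch: {len(preds)} vs {len(truth)}")
    scores = np.array([np.asarray(p.probabilities, dtype=float) for p in preds])
    truth_idx = np.array([t.channel_index for t in truth])
    if len(set(truth_idx.tolist())) < 2:
        raise ValueError("need at least two classes in the truth labels")
    return _report(scores, truth_idx, ALL_CLASSES)
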