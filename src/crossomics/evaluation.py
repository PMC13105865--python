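"""Discrimination, calibration and inferential statistics for CV results.

Discrimination metrics delegate to scikit-learn.  Calibration (ECE, Brier,
NLL) and the variance-corrected repeated-cross-validation t-test are written
out explicitly because their conventions are part of this package's contract:

* ECE uses M equal-width confidence bins on (0, 1]; confidence is the maximum
  predicted class probability.
* Brier is the multiclass sum of squared deviations from the one-hot label,
  averaged over samples.
* The corrected t-test inflates the naive variance of per-fold metric
  differences by the test-to-train ratio ρ (1/4 for five-fold CV), following
  the Nadeau–Bengio correction for repeated cross-validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import (accuracy_score, average_precision_score,
                             balanced_accuracy_score, confusion_matrix,
                             matthews_corrcoef, precision_recall_fscore_support,
                             roc_auc_score)

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ confusion
@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # K × K, rows = true, cols = predicted
    class_labels: list[int]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row_normalized(self) -> np.ndarray:
        n = self.supports.astype(float)
        out = np.zeros_like(self.counts, dtype=float)
        nz = n > 0
        out[nz] = self.counts[nz] / n[nz, None]
        return out

    def per_class_recall(self) -> np.ndarray:
        return np.diag(self.row_normalized())


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_and_prf(labels, predictions, num_classes: int | None = None):
    """Confusion counts plus per-class precision / recall / F1."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if num_classes is None:
        num_classes = int(max(labels.max(), predictions.max())) + 1
    cls = list(range(num_classes))
    cm = ConfusionMatrix(counts=confusion_matrix(labels, predictions, labels=cls),
                         class_labels=cls)
    precision, recall, f1, _ = precision_recall_fscore_support(
        labels, predictions, labels=cls, zero_division=0)
    return cm, precision, recall, f1


def macro_weighted_f1(per_class_f1, supports) -> tuple[float, float]:
    """Unweighted and support-weighted means of the per-class F1 scores."""
    f1 = np.asarray(per_class_f1, dtype=float)
    n = np.asarray(supports, dtype=float)
    return float(f1.mean()), float((n / n.sum() * f1).sum())


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-class recall over classes with non-zero support."""
    recalls = cm.per_class_recall()
    present = cm.supports > 0
    return float(recalls[present].mean())


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient from confusion counts."""
    c = cm.counts.astype(float)
    t = c.sum(axis=1)   # true supports
    p = c.sum(axis=0)   # predicted supports
    n = c.sum()
    cov = c.trace() * n - t @ p
    denom = math.sqrt(n * n - p @ p) * math.sqrt(n * n - t @ t)
    return float(cov / denom) if denom else 0.0


# ----------------------------------------------------------------- reporting
@dataclass
class MetricReport:
    accuracy: float
    balanced_accuracy: float
    mcc: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray
    macro_f1: float
    weighted_f1: float
    auroc: float
    auprc: float

    def to_dict(self) -> dict:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        return d


def ovr_macro_auc(prob_table: np.ndarray, labels) -> tuple[float, float]:
    """One-vs-rest AUROC and AUPRC, macro-averaged over evaluable classes.

    A class absent from the labels (or covering all of them) has no defined
    ROC and is excluded from the macro mean with a logged notice.
    """
    probs = np.asarray(prob_table, dtype=float)
    labels = np.asarray(labels)
    aurocs, auprcs = [], []
    for k in range(probs.shape[1]):
        pos = (labels == k).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            logger.info("class %d has no positives/negatives; excluded from AUC", k)
            continue
        aurocs.append(roc_auc_score(pos, probs[:, k]))
        auprcs.append(average_precision_score(pos, probs[:, k]))
    return float(np.mean(aurocs)), float(np.mean(auprcs))


def metric_report(labels, prob_table: np.ndarray,
                  num_classes: int | None = None) -> MetricReport:
    probs = np.asarray(prob_table, dtype=float)
    labels = np.asarray(labels)
    predictions = probs.argmax(axis=1)
    cm, precision, recall, f1 = confusion_and_prf(labels, predictions, num_classes)
    macro, weighted = macro_weighted_f1(f1, cm.supports)
    auroc, auprc = ovr_macro_auc(probs, labels)
    return MetricReport(
        accuracy=float(accuracy_score(labels, predictions)),
        balanced_accuracy=balanced_accuracy(cm),
        mcc=float(matthews_corrcoef(labels, predictions)),
        per_class_precision=precision, per_class_recall=recall, per_class_f1=f1,
        macro_f1=macro, weighted_f1=weighted,
        auroc=auroc, auprc=auprc)


# ---------------------------------------------------------------- calibration
@dataclass
class CalibrationReport:
    n_bins: int
    bin_confidence: np.ndarray
    bin_accuracy: np.ndarray
    bin_counts: np.ndarray
    ece: float
    brier: float
    nll: float

    def to_dict(self) -> dict:
        return {"n_bins": self.n_bins, "ece": self.ece, "brier": self.brier,
                "nll": self.nll, "bin_confidence": self.bin_confidence.tolist(),
                "bin_accuracy": self.bin_accuracy.tolist(),
                "bin_counts": self.bin_counts.tolist()}


def calibration_report(prob_table: np.ndarray, labels,
                       n_bins: int = 15) -> CalibrationReport:
    """ECE over equal-width confidence bins, plus Brier score and NLL."""
    probs = np.asarray(prob_table, dtype=float)
    labels = np.asarray(labels)
    n, k = probs.shape
    conf = probs.max(axis=1)
    correct = (probs.argmax(axis=1) == labels).astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # bins are half-open on the left, (lo, hi]; searchsorted('left') gives that
    bin_ix = np.clip(np.searchsorted(edges, conf, side="left") - 1, 0, n_bins - 1)
    bin_counts = np.bincount(bin_ix, minlength=n_bins)
    sum_conf = np.bincount(bin_ix, weights=conf, minlength=n_bins)
    sum_acc = np.bincount(bin_ix, weights=correct, minlength=n_bins)
    occupied = bin_counts > 0
    bin_conf = np.where(occupied, sum_conf / np.maximum(bin_counts, 1), 0.0)
    bin_acc = np.where(occupied, sum_acc / np.maximum(bin_counts, 1), 0.0)
    ece = float(np.sum(bin_counts / n * np.abs(bin_acc - bin_conf)))
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    brier = float(((probs - onehot) ** 2).sum(axis=1).mean())
    nll = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean())
    return CalibrationReport(n_bins=n_bins, bin_confidence=bin_conf,
                             bin_accuracy=bin_acc, bin_counts=bin_counts,
                             ece=ece, brier=brier, nll=nll)


# ---------------------------------------------- corrected repeated-CV inference
@dataclass
class PairedComparison:
    diffs: np.ndarray
    mean_diff: float
    corrected_se: float
    t_stat: float
    p_value: float
    ci_low: float
    ci_high: float
    rho: float
    degenerate: bool = False


def nadeau_bengio_test(diffs, k: int = 5, r: int = 5,
                       rho: float = 0.25) -> PairedComparison:
    """Variance-corrected paired t-test over k·r per-fold metric differences.

    t = d̄ / sqrt((1/(k·r) + ρ) s²) with s² the sample variance of the
    differences and k·r − 1 degrees of freedom.  ρ is the test-to-train ratio
    (1/4 for five-fold CV).  Zero-variance difference vectors are degenerate:
    p is reported as exactly 1.0 when d̄ = 0 and 0.0 otherwise, with a warning.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n != k * r:
        raise ValueError(f"expected {k * r} differences, got {n}")
    mean = float(d.mean())
    var = float(d.var(ddof=1)) if n > 1 else 0.0
    if var == 0.0:
        logger.warning("zero-variance differences: degenerate corrected t-test")
        p = 1.0 if mean == 0.0 else 0.0
        return PairedComparison(diffs=d, mean_diff=mean, corrected_se=0.0,
                                t_stat=np.inf if mean else 0.0, p_value=p,
                                ci_low=mean, ci_high=mean, rho=rho,
                                degenerate=True)
    se = math.sqrt((1.0 / n + rho) * var)
    t = mean / se
    df = n - 1
    p = float(2 * sps.t.sf(abs(t), df))
    half = float(sps.t.ppf(0.975, df) * se)
    return PairedComparison(diffs=d, mean_diff=mean, corrected_se=se, t_stat=t,
                            p_value=p, ci_low=mean - half, ci_high=mean + half,
                            rho=rho)


def relative_drop_percent(full: float, variant: float) -> float:
    """Relative change 100·(full − variant)/full, as a percentage.

    This is the ΔAcc convention used when comparing an ablated variant with
    the full model (e.g. 0.912 → 0.880 gives 3.51%).
    """
    return 100.0 * (full - variant) / full


# --------------------------------------------------------------- OOF helpers
def prob_columns(oof: pd.DataFrame) -> list[str]:
    return sorted((c for c in oof.columns if c.startswith("p") and c[1:].isdigit()),
                  key=lambda c: int(c[1:]))


def per_fold_metric(oof: pd.DataFrame, metric: str = "accuracy") -> pd.DataFrame:
    """One metric value per (repeat, fold) from an out-of-fold table."""
    cols = prob_columns(oof)
    rows = []
    for (rep, fold), part in oof.groupby(["repeat", "fold"]):
        probs = part[cols].to_numpy()
        labels = part["label"].to_numpy()
        if metric == "accuracy":
            val = float((probs.argmax(axis=1) == labels).mean())
        elif metric == "macro_f1":
            rep_ = metric_report(labels, probs)
            val = rep_.macro_f1
        elif metric == "auroc":
            val, _ = ovr_macro_auc(probs, labels)
        elif metric == "auprc":
            _, val = ovr_macro_auc(probs, labels)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        rows.append({"repeat": rep, "fold": fold, metric: val})
    return pd.DataFrame(rows).sort_values(["repeat", "fold"]).reset_index(drop=True)


def compare_oof(oof_a: pd.DataFrame, oof_b: pd.DataFrame, metric: str = "accuracy",
                k: int = 5, r: int = 5, rho: float = 0.25) -> PairedComparison:
    """Corrected paired comparison of two methods sharing the same fold plan."""
    a = per_fold_metric(oof_a, metric)[metric].to_numpy()
    b = per_fold_metric(oof_b, metric)[metric].to_numpy()
    return nadeau_bengio_test(a - b, k=k, r=r, rho=rho)
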