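"""Confusion-matrix metrics in the two aggregation flavours.

Per class (one-vs-rest): Accuracy = (TP+TN)/(TP+TN+FP+FN), Precision =
TP/(TP+FP), Recall = TP/(TP+FN), F1 = harmonic mean of Precision and Recall.
``macro`` averages classes with equal weight; ``overall`` reports the
sample-level accuracy together with support-weighted Precision/Recall/F1
(pure micro-averaging would collapse all three onto accuracy for a
single-label multiclass problem, which is why the sample-level flavour is
support-weighted). Per-class metrics that are undefined (zero support or no
predicted positives) are reported as NaN and excluded from macro means with
a warning, rather than zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with true classes on rows, predicted on columns."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    return conf


def binary_counts(conf: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for class c."""
    tp = conf[c, c]
    fp = conf[:, c].sum() - tp
    fn = conf[c, :].sum() - tp
    tn = conf.sum() - tp - fp - fn
    return int(tp), int(fp), int(fn), int(tn)


def per_class_metrics(conf: np.ndarray) -> pd.DataFrame:
    """Accuracy/Precision/Recall/F1 per class; undefined entries are NaN."""
    rows = []
    n = conf.sum()
    for c in range(conf.shape[0]):
        tp, fp, fn, tn = binary_counts(conf, c)
        support = tp + fn
        acc = (tp + tn) / n if n else np.nan
        if support == 0:
            warnings.warn(f"class {c} absent from the evaluation set; "
                          "its metrics are undefined")
            prec = np.nan if tp + fp == 0 else tp / (tp + fp)
            rec = np.nan
        else:
            prec = tp / (tp + fp) if tp + fp else np.nan
            if np.isnan(prec):
                warnings.warn(f"class {c} never predicted; precision undefined")
            rec = tp / (tp + fn)
        if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
            f1 = np.nan if (np.isnan(prec) or np.isnan(rec)) else 0.0
        else:
            f1 = 2 * prec * rec / (prec + rec)
        rows.append({"class": c, "support": support, "accuracy": acc,
                     "precision": prec, "recall": rec, "f1": f1})
    return pd.DataFrame(rows).set_index("class")


def macro_metrics(per_class: pd.DataFrame) -> dict:
    """Unweighted class means, NaN (undefined) entries excluded."""
    return {m: float(np.nanmean(per_class[m])) for m in METRIC_NAMES}


def overall_metrics(conf: np.ndarray) -> dict:
    """Sample-level accuracy plus support-weighted P/R/F1."""
    per = per_class_metrics(conf)
    support = per["support"].to_numpy(dtype=float)
    w = support / support.sum() if support.sum() else support
    out = {"accuracy": float(np.trace(conf) / conf.sum()) if conf.sum() else np.nan}
    for m in ("precision", "recall", "f1"):
        vals = per[m].to_numpy(dtype=float)
        ok = ~np.isnan(vals) & (support > 0)
        out[m] = float((vals[ok] * w[ok]).sum() / w[ok].sum()) if ok.any() else np.nan
    return out


@dataclass
class EvalReport:
    """Confusion matrix plus per-class, macro and sample-level metrics."""

    confusion: np.ndarray
    per_class: pd.DataFrame
    macro: dict
    overall: dict
    n: int

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int) -> "EvalReport":
        conf = confusion_matrix(y_true, y_pred, n_classes)
        per = per_class_metrics(conf)
        return cls(confusion=conf, per_class=per, macro=macro_metrics(per),
                   overall=overall_metrics(conf), n=int(conf.sum()))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.reset_index().to_dict("records"),
            "macro": self.macro,
            "overall": self.overall,
        }


def aggregate_reports(reports: list[EvalReport], flavour: str = "overall") -> dict:
    """Fold-wise mean +/- sd of each metric, the CV reporting convention."""
    stats = {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, flavour)[m] for r in reports], dtype=float)
        stats[f"{m}_mean"] = float(np.nanmean(vals))
        stats[f"{m}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
    return stats
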