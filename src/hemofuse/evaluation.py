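"""Confusion matrices and per-class classification metrics.

Metrics follow the one-vs-rest convention used throughout the ICH
literature: for each class, TP/FP/FN/TN are counted against "all other
classes" and

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)        accuracy    = (TP + TN) / N

Per-class accuracy is deliberately the one-vs-rest form — with five
haemorrhage subtypes it differs from overall accuracy and is the
definition consistent with published per-class tables.  Macro averages
are unweighted means over classes.  Values are kept at full precision
internally; reports round half-even to 4 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICH_CLASSES",
    "ClassMetrics",
    "confusion",
    "per_class_metrics",
    "macro_average",
    "metrics_table",
    "write_report",
]

ICH_CLASSES = ("IVT", "IPC", "SAD", "EPI", "SBD")
METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy")


def confusion(true_labels, predicted_labels, class_order=None) -> pd.DataFrame:
    """Square count matrix, rows = true class, columns = predicted class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    order = list(class_order) if class_order is not None else sorted(
        set(t.tolist()) | set(p.tolist())
    )
    index = {c: i for i, c in enumerate(order)}
    unknown = [x for x in set(t.tolist()) | set(p.tolist()) if x not in index]
    if unknown:
        raise ValueError(f"labels outside class order: {unknown}")
    cm = np.zeros((len(order), len(order)), dtype=int)
    for a, b in zip(t, p):
        cm[index[a], index[b]] += 1
    return pd.DataFrame(cm, index=order, columns=order)


@dataclass
class ClassMetrics:
    """Per-class metric table plus degeneracy flags for 0/0 divisions."""

    table: pd.DataFrame            # classes x (sensitivity..accuracy)
    degenerate: pd.DataFrame       # same shape, bool

    @property
    def classes(self) -> list:
        return list(self.table.index)

    def macro(self) -> pd.Series:
        return self.table.mean(axis=0)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_metrics(cm: pd.DataFrame) -> ClassMetrics:
    """One-vs-rest sensitivity/specificity/precision/accuracy per class."""
    mat = cm.to_numpy()
    n = mat.sum()
    if n <= 0:
        raise ValueError("confusion matrix is empty")
    rows = {}
    flags = {}
    for i, cls in enumerate(cm.index):
        tp = mat[i, i]
        fn = mat[i, :].sum() - tp
        fp = mat[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens, f1 = _safe_div(tp, tp + fn)
        spec, f2 = _safe_div(tn, tn + fp)
        prec, f3 = _safe_div(tp, tp + fp)
        acc, f4 = _safe_div(tp + tn, n)
        rows[cls] = [sens, spec, prec, acc]
        flags[cls] = [f1, f2, f3, f4]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_NAMES)
    degenerate = pd.DataFrame.from_dict(flags, orient="index", columns=METRIC_NAMES)
    return ClassMetrics(table=table, degenerate=degenerate)


def macro_average(metrics: ClassMetrics) -> pd.Series:
    """Unweighted mean of each metric over classes."""
    return metrics.macro()


def round4(x) -> float:
    """Report-time rounding: half-even to 4 decimals."""
    return float(np.round(x, 4))


def metrics_table(metrics: ClassMetrics, decimals: int = 4) -> pd.DataFrame:
    """Per-class rows plus an Average row, rounded for reporting."""
    table = metrics.table.round(decimals)
    table.loc["Average"] = metrics.macro().round(decimals)
    return table


def write_report(metrics: ClassMetrics, csv_path=None, md_path=None) -> pd.DataFrame:
    out = metrics_table(metrics)
    if csv_path is not None:
        out.to_csv(csv_path, index_label="class")
    if md_path is not None:
        with open(md_path, "w") as fh:
            fh.write(out.to_markdown())
            fh.write("\n")
    return out
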