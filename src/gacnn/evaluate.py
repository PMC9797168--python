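"""Classification metrics: confusion matrix, accuracy, precision/recall,
Cohen's kappa, and sweep report tables.

All metrics are computed from the K x K confusion matrix C (rows = true
label, columns = predicted label). Accuracy is trace(C)/n. Precision and
recall are per-class one-vs-rest ratios combined by micro averaging
(pooled TP/FP/FN counts — under which precision = recall = accuracy) or
macro averaging (unweighted per-class mean). Cohen's kappa is

    kappa = (p0 - pe) / (1 - pe),
    pe = (a1*b1 + ... + aK*bK) / n^2,

with p0 the observed agreement (accuracy), a_k the true marginals and b_k
the predicted marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["confusion", "accuracy", "precision_recall", "kappa",
           "MetricsReport", "report", "sweep_report"]


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix C[t, p] of (true t, predicted p) pairs."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= n_classes
                        or y_pred.min() < 0 or y_pred.max() >= n_classes):
        raise ValueError(f"labels out of range 0..{n_classes - 1}")
    C = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(C, (y_true, y_pred), 1)
    return C


def accuracy(C: np.ndarray) -> float:
    """trace(C) / n: proportion of correctly classified samples."""
    C = np.asarray(C)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(C) / n)


def precision_recall(C: np.ndarray, averaging: str = "micro") -> tuple[float, float]:
    """(precision, recall) with micro or macro averaging.

    Micro pools one-vs-rest counts, which forces precision = recall =
    accuracy in the multi-class single-label setting. Macro averages
    per-class ratios; classes absent from both margins are excluded with
    a warning.
    """
    C = np.asarray(C, dtype=float)
    tp = np.diag(C)
    fp = C.sum(axis=0) - tp
    fn = C.sum(axis=1) - tp
    if averaging == "micro":
        p = tp.sum() / (tp.sum() + fp.sum())
        r = tp.sum() / (tp.sum() + fn.sum())
        return float(p), float(r)
    if averaging != "macro":
        raise ValueError("averaging must be 'micro' or 'macro'")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_p = tp / (tp + fp)
        per_r = tp / (tp + fn)
    valid_p, valid_r = np.isfinite(per_p), np.isfinite(per_r)
    if not valid_p.all() or not valid_r.all():
        warnings.warn("empty class excluded from macro averaging")
    return float(per_p[valid_p].mean()), float(per_r[valid_r].mean())


def kappa(C: np.ndarray) -> tuple[float, float, float]:
    """Cohen's kappa with its components: (kappa, p0, pe)."""
    C = np.asarray(C, dtype=float)
    n = C.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p0 = np.trace(C) / n
    a = C.sum(axis=1)   # true marginals
    b = C.sum(axis=0)   # predicted marginals
    pe = float((a * b).sum() / (n * n))
    if pe >= 1.0:
        raise ValueError("degenerate single-cell matrix: kappa undefined")
    return float((p0 - pe) / (1.0 - pe)), float(p0), pe


@dataclass(frozen=True)
class MetricsReport:
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    kappa: float
    p0: float
    pe: float
    averaging: str = "micro"

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "kappa": self.kappa}


def report(y_true, y_pred, n_classes: int = 5,
           averaging: str = "micro") -> MetricsReport:
    """Full metrics report from raw label vectors."""
    C = confusion(y_true, y_pred, n_classes)
    prec, rec = precision_recall(C, averaging)
    k, p0, pe = kappa(C)
    return MetricsReport(confusion=C, accuracy=accuracy(C), precision=prec,
                         recall=rec, kappa=k, p0=p0, pe=pe,
                         averaging=averaging)


def sweep_report(results: dict, key_name: str = "labeling_rate",
                 out_csv: str | None = None) -> pd.DataFrame:
    """Aggregate metric dicts keyed by a swept parameter into a tidy table.

    ``results`` maps each parameter value (labeling rate or lambda) to a
    list of per-run metric dicts (e.g. ``MetricsReport.as_dict()`` per fold
    or seed). Output rows are sorted ascending by the parameter and carry
    mean and sd columns per metric.
    """
    if not results:
        raise ValueError("no results to report")
    rows = []
    for key in sorted(results):
        runs = results[key]
        if isinstance(runs, dict):
            runs = [runs]
        metrics = sorted({m for run in runs for m in run})
        row = {key_name: key, "n_runs": len(runs)}
        for m in metrics:
            vals = np.array([run[m] for run in runs if m in run], dtype=float)
            row[f"{m}_mean"] = vals.mean()
            row[f"{m}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
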