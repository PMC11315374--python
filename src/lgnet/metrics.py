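"""Multi-class evaluation: one-vs-rest confusion counts and Acc/Pre/Rec/F1.

Precision, recall and F1 are computed per class from the one-vs-rest counts

    Pre = TP / (TP + FP),  Rec = TP / (TP + FN),  F1 = 2TP / (2TP + FP + FN)

and macro-averaged (classes weighted equally); micro and support-weighted
variants are available behind the ``averaging`` flag.  Accuracy is the
overall fraction of exactly correct predictions.  Classes with no predicted
positives contribute precision 0 and are flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

__all__ = ["ConfusionCounts", "Scores", "confusion", "scores", "format_table"]


@dataclass
class ConfusionCounts:
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    num_classes: int
    num_samples: int

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix

    def __post_init__(self):
        self._matrix = None


def confusion(labels, predictions, num_classes: int) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise DataError(
            f"labels and predictions differ in length: {labels.shape} vs "
            f"{predictions.shape}")
    for name, arr in (("labels", labels), ("predictions", predictions)):
        bad = np.flatnonzero((arr < 0) | (arr >= num_classes))
        if bad.size:
            raise DataError(
                f"{name}[{bad[0]}] = {arr[bad[0]]} outside [0, {num_classes})")
    n = labels.size
    mat = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(mat, (labels, predictions), 1)
    tp = np.diag(mat).copy()
    fp = mat.sum(axis=0) - tp
    fn = mat.sum(axis=1) - tp
    tn = n - tp - fp - fn
    counts = ConfusionCounts(tp, fp, fn, tn, num_classes, n)
    counts._matrix = mat
    return counts


@dataclass
class Scores:
    """Fractions in [0, 1]; `as_percent()` gives the reporting scale."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict
    averaging: str
    zero_prediction_classes: tuple[int, ...]

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * getattr(self, k)
                for k in ("accuracy", "precision", "recall", "f1")}


def _safe_div(a, b):
    return np.divide(a, b, out=np.zeros_like(a, dtype=np.float64),
                     where=np.asarray(b) != 0)


def scores(counts: ConfusionCounts, averaging: str = "macro") -> Scores:
    if counts.num_samples == 0:
        raise DataError("cannot score an empty prediction set")
    tp, fp, fn, tn = (counts.tp.astype(np.float64), counts.fp.astype(np.float64),
                      counts.fn.astype(np.float64), counts.tn.astype(np.float64))
    pre_k = _safe_div(tp, tp + fp)
    rec_k = _safe_div(tp, tp + fn)
    f1_k = _safe_div(2 * tp, 2 * tp + fp + fn)
    acc_k = (tp + tn) / counts.num_samples
    accuracy = float(tp.sum() / counts.num_samples)
    support = tp + fn
    if averaging == "macro":
        pre, rec, f1 = pre_k.mean(), rec_k.mean(), f1_k.mean()
    elif averaging == "micro":
        pre = _safe_div(tp.sum(), (tp + fp).sum())
        rec = _safe_div(tp.sum(), (tp + fn).sum())
        f1 = _safe_div(2 * tp.sum(), (2 * tp + fp + fn).sum())
    elif averaging == "weighted":
        w = support / support.sum()
        pre, rec, f1 = (pre_k * w).sum(), (rec_k * w).sum(), (f1_k * w).sum()
    else:
        raise DataError(f"unknown averaging rule {averaging!r}")
    zero_pred = tuple(int(k) for k in np.flatnonzero((tp + fp) == 0))
    per_class = {k: {"accuracy": float(acc_k[k]), "precision": float(pre_k[k]),
                     "recall": float(rec_k[k]), "f1": float(f1_k[k]),
                     "support": int(support[k])}
                 for k in range(counts.num_classes)}
    return Scores(accuracy, float(pre), float(rec), float(f1),
                  per_class, averaging, zero_pred)


def format_table(sc: Scores, vocabulary: list[str] | None = None,
                 sep: str = "\t") -> str:
    """Per-class rows plus a summary row, percentages to 2 decimals."""
    lines = [sep.join(["class", "acc%", "pre%", "rec%", "f1%", "support"])]
    for k, row in sc.per_class.items():
        name = vocabulary[k] if vocabulary else str(k)
        lines.append(sep.join([name] + [f"{100 * row[m]:.2f}" for m in
                                        ("accuracy", "precision", "recall", "f1")]
                              + [str(row["support"])]))
    pct = sc.as_percent()
    lines.append(sep.join([f"{sc.averaging}-avg",
                           f"{pct['accuracy']:.2f}", f"{pct['precision']:.2f}",
                           f"{pct['recall']:.2f}", f"{pct['f1']:.2f}", ""]))
    return "\n".join(lines)
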