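"""Confusion matrices and the multiclass precision/recall/F metric suite.

For class *i* with true positives TP (the diagonal cell), false positives
FP (its column sum minus TP) and false negatives FN (its row sum minus TP):

.. math::

    \\mathrm{Re}_i = \\frac{TP_i}{TP_i + FN_i}, \\qquad
    \\mathrm{Pr}_i = \\frac{TP_i}{TP_i + FP_i}, \\qquad
    F_i = \\frac{2\\,\\mathrm{Pr}_i\\,\\mathrm{Re}_i}{\\mathrm{Pr}_i + \\mathrm{Re}_i}

The macro-averaged F-measure is the unweighted mean of the per-class
F-measures, giving equal weight to rare behaviours; the per-class error is
``FN / (TP + FN) = 1 - recall``.  Macro-F averages *unrounded* class Fs;
rounding happens only at report time.

The package ships the six reference confusion matrices (one per base
learner plus the voting ensemble) from the original captive-trial test set
as integer CSV fixtures, loadable with :func:`load_reference_matrix`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from sharketho.io import CLASSES, LabelTrack

REFERENCE_MODELS = ("LR", "ANN", "RFG", "RFE", "GB", "VE")


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are actual classes, columns predicted."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


@dataclass
class MetricsReport:
    """Per-class TP/FP/FN, precision, recall, F and class error, plus macro-F."""

    per_class: pd.DataFrame
    macro_f: float
    n_classes: int

    def round(self, ndigits: int = 3) -> pd.DataFrame:
        out = self.per_class.copy()
        for col in ("precision", "recall", "f_measure", "class_error"):
            out[col] = out[col].round(ndigits)
        return out

    def summary(self, ndigits: int = 3) -> str:
        lines = [self.round(ndigits).to_string()]
        lines.append(f"macro-averaged F: {self.macro_f:.{ndigits}f}")
        return "\n".join(lines)


def confusion_counts(actual, predicted, class_order=CLASSES) -> np.ndarray:
    actual = np.asarray(actual, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if actual.shape != predicted.shape:
        raise ValueError(
            f"actual ({actual.shape}) and predicted ({predicted.shape}) lengths differ"
        )
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return counts


def confusion(actual: LabelTrack, predicted: LabelTrack,
              class_order: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Tally an actual-vs-predicted label pair into a confusion matrix."""
    a = actual.labels if isinstance(actual, LabelTrack) else actual
    p = predicted.labels if isinstance(predicted, LabelTrack) else predicted
    return ConfusionMatrix(confusion_counts(a, p, class_order), class_order)


def _prf(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray):
    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        re = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f = np.where(pr + re > 0, 2 * pr * re / np.maximum(pr + re, 1e-300), 0.0)
    return pr, re, f


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall, F, class error per class and the macro-averaged F."""
    tp, fp, fn = cm.tp().astype(float), cm.fp().astype(float), cm.fn().astype(float)
    pr, re, f = _prf(tp, fp, fn)
    class_error = np.where(tp + fn > 0, fn / np.maximum(tp + fn, 1), 0.0)
    per_class = pd.DataFrame(
        {
            "TP": tp.astype(int), "FP": fp.astype(int), "FN": fn.astype(int),
            "precision": pr, "recall": re, "f_measure": f, "class_error": class_error,
        },
        index=list(cm.class_order),
    )
    return MetricsReport(per_class=per_class, macro_f=float(f.mean()),
                         n_classes=len(cm.class_order))


def macro_f_from_counts(counts: np.ndarray) -> float:
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    return float(_prf(tp, fp, fn)[2].mean())


def predicted_vs_actual_ratio(cm: ConfusionMatrix, cls: str) -> float:
    """Predicted count as a percentage of the actual count for one class.

    A model over-predicting a rare behaviour inflates this above 100%
    (precision loss); under-prediction pushes it below 100%.
    """
    i = cm.class_order.index(cls)
    actual = cm.counts[i, :].sum()
    if actual == 0:
        raise ValueError(f"class {cls!r} has no actual observations")
    predicted = cm.counts[:, i].sum()
    return 100.0 * predicted / actual


# ---------------------------------------------------------------------------
# packaged reference fixtures

def _fixture_dir():
    return resources.files("sharketho") / "fixtures"


def load_reference_matrix(model: str) -> ConfusionMatrix:
    """Load a packaged reference test-set confusion matrix (LR/ANN/RFG/RFE/GB/VE).

    File integrity is checked against the shipped SHA-256 manifest.
    """
    if model not in REFERENCE_MODELS:
        raise ValueError(f"unknown reference model {model!r}; expected one of {REFERENCE_MODELS}")
    fdir = _fixture_dir()
    raw = (fdir / f"confusion_{model}.csv").read_bytes()
    checksums = json.loads((fdir / "checksums.json").read_text())
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[f"confusion_{model}.csv"]:
        raise ValueError(f"fixture confusion_{model}.csv failed its checksum")
    df = pd.read_csv((fdir / f"confusion_{model}.csv").open(), index_col=0)
    if list(df.columns) != list(CLASSES) or list(df.index) != list(CLASSES):
        raise ValueError(f"fixture confusion_{model}.csv has unexpected layout")
    return ConfusionMatrix(df.to_numpy(dtype=int))


def reference_report(model: str) -> MetricsReport:
    """Metric report for one packaged reference confusion matrix."""
    return metrics(load_reference_matrix(model))
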