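"""Multi-class classification metrics on confusion matrices.

Accuracy alone is misleading on imbalanced class distributions, so the
macro F-score (unweighted mean over classes of the per-class harmonic mean
of precision and recall) and the G-mean (geometric mean of per-class
recalls) are reported alongside it.  An accuracy value clearly above F or G
flags a classifier leaning on the majority classes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "confusion_matrix", "accuracy", "f_score", "g_mean"]


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """k x k count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("counts must be k x k matching the class list")
        if np.any(c < 0):
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def recalls(self) -> np.ndarray:
        """Per-class recall; 0 where the class has no true samples."""
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.diag(self.counts) / row
        return np.where(row > 0, r, 0.0)

    def precisions(self) -> np.ndarray:
        """Per-class precision; 0 where the class is never predicted."""
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.diag(self.counts) / col
        return np.where(col > 0, p, 0.0)


def confusion_matrix(y_true, y_pred, classes: Sequence[str]) -> ConfusionMatrix:
    """Count (true, predicted) pairs over a fixed, ordered class list."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in idx:
            raise ValueError(f"unknown true label {t!r}")
        if p not in idx:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def f_score(cm: ConfusionMatrix) -> float:
    """Macro F-score: unweighted mean over classes of 2 R P / (R + P).

    Zero-denominator conventions: recall or precision with an empty
    denominator is 0, and a class with R + P = 0 contributes F_i = 0.
    """
    if cm.k < 2:
        raise ValueError("need at least 2 classes")
    r, p = cm.recalls(), cm.precisions()
    denom = r + p
    with np.errstate(invalid="ignore", divide="ignore"):
        f_i = 2.0 * r * p / denom
    f_i = np.where(denom > 0, f_i, 0.0)
    return float(f_i.mean())


def g_mean(cm: ConfusionMatrix) -> float:
    """Geometric mean of per-class recalls; 0 if any class is entirely missed."""
    if cm.k < 2:
        raise ValueError("need at least 2 classes")
    r = cm.recalls()
    if np.any(r == 0):
        return 0.0
    return float(np.exp(np.log(r).mean()))
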