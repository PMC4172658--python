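"""Fuzzy discretization of expression values and per-class pattern discovery.

Each gene gets three membership functions — Low, Medium, High — parameterized
by its across-sample mean ``c`` and standard deviation ``s``.  A value's
memberships are thresholded at ``zeta`` to give one of five linguistic labels
(Low, Low-Medium, Medium, Medium-High, High); per class, genes whose dominant
label reaches frequency ``piVal`` form that class's *fuzzy pattern* (FP).
The union of all FPs is the selected feature set handed to the ranking forest.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np

from .dataset import ExpressionDataset, ValidationError

logger = logging.getLogger(__name__)

# Fixed label order; also the tie-break order wherever ties can occur.
LABELS = ("Low", "Low-Medium", "Medium", "Medium-High", "High")
_SINGLE = ("Low", "Medium", "High")

__all__ = [
    "LABELS",
    "MembershipFamily",
    "GaussianSigmoidFamily",
    "MembershipModel",
    "FuzzyPattern",
    "fit_membership_model",
    "assign_label",
    "assign_labels",
    "discretize",
    "discover_fuzzy_patterns",
    "selected_features",
    "write_label_matrix",
    "write_patterns",
    "read_patterns",
]


class MembershipFamily:
    """Interface for a per-gene membership-function family.

    Implementations map arrays of expression values to the three membership
    degrees given a gene's center ``c`` and spread ``s``.  The family is
    pluggable so alternative curve shapes (e.g. polynomial approximations of
    the same targets) can be swapped in without touching discretization or
    pattern discovery.
    """

    def memberships(self, x, c: float, s: float):
        """Return (mu_Low, mu_Medium, mu_High) for ``x`` (scalar or array)."""
        raise NotImplementedError


class GaussianSigmoidFamily(MembershipFamily):
    """Default family: Gaussian bell for Medium, opposed sigmoids for Low/High.

    mu_Medium(x) = exp(-(x-c)^2 / (2 s^2)) peaks at the gene mean; the
    sigmoids mu_Low / mu_High cross 0.5 at the mean with steepness a = 2/s,
    so Low is non-increasing and High non-decreasing in x.
    """

    def memberships(self, x, c: float, s: float):
        x = np.asarray(x, dtype=np.float64)
        z = (x - c) / s
        mu_m = np.exp(-0.5 * z * z)
        # 2/s steepness => sigmoid argument is 2z
        mu_h = 1.0 / (1.0 + np.exp(-2.0 * z))
        mu_l = 1.0 - mu_h
        return mu_l, mu_m, mu_h


@dataclasses.dataclass(frozen=True)
class MembershipModel:
    """Per-gene (center, spread) parameters plus the membership family."""

    feature_ids: tuple[str, ...]
    centers: np.ndarray
    spreads: np.ndarray
    family: MembershipFamily

    def _index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def memberships(self, feature_id: str, x):
        """(mu_Low, mu_Medium, mu_High) of ``x`` under the gene's functions."""
        i = self._index(feature_id)
        return self.family.memberships(x, self.centers[i], self.spreads[i])


def fit_membership_model(
    ds: ExpressionDataset, family: MembershipFamily | None = None
) -> MembershipModel:
    """Fit per-gene membership functions: c = sample mean, s = sample sd.

    Statistics are computed on the matrix handed in — inside the evaluation
    harness that is the training split only, so no test information leaks
    into the discretization.
    """
    c = ds.values.mean(axis=1)
    s = ds.values.std(axis=1, ddof=1)
    if np.any(s == 0):
        bad = ds.feature_ids[int(np.argmax(s == 0))]
        raise ValidationError(
            f"feature {bad!r} is constant (sd = 0); remove it first with "
            "filter_low_variance"
        )
    return MembershipModel(
        ds.feature_ids, c, s, family if family is not None else GaussianSigmoidFamily()
    )


def assign_label(mu: Sequence[float], zeta: float) -> str:
    """Convert a membership triple (mu_L, mu_M, mu_H) into one linguistic label.

    The active set A = {label : mu >= zeta}.  A singleton maps to itself;
    {Low, Medium} -> Low-Medium and {Medium, High} -> Medium-High; an empty
    A falls back to the argmax label (ties broken Low < Medium < High);
    the non-adjacent activations ({Low, High} or all three) map to Medium.
    Total for every finite input.
    """
    mu_l, mu_m, mu_h = float(mu[0]), float(mu[1]), float(mu[2])
    active = (mu_l >= zeta, mu_m >= zeta, mu_h >= zeta)
    if active == (True, False, False):
        return "Low"
    if active == (False, True, False):
        return "Medium"
    if active == (False, False, True):
        return "High"
    if active == (True, True, False):
        return "Low-Medium"
    if active == (False, True, True):
        return "Medium-High"
    if active == (False, False, False):
        return _SINGLE[int(np.argmax([mu_l, mu_m, mu_h]))]
    return "Medium"  # {Low, High} or all three: non-adjacent, collapse to Medium


def assign_labels(mu_l, mu_m, mu_h, zeta: float) -> np.ndarray:
    """Vectorized :func:`assign_label` over arrays of membership triples.

    Returns an int8 array of indices into :data:`LABELS`.
    """
    mu_l, mu_m, mu_h = (np.asarray(a) for a in (mu_l, mu_m, mu_h))
    al, am, ah = mu_l >= zeta, mu_m >= zeta, mu_h >= zeta
    out = np.full(mu_l.shape, 2, dtype=np.int8)  # default Medium
    n_active = al.astype(int) + am.astype(int) + ah.astype(int)
    out[al & (n_active == 1)] = 0
    out[am & (n_active == 1)] = 2
    out[ah & (n_active == 1)] = 4
    out[al & am & (n_active == 2)] = 1
    out[am & ah & (n_active == 2)] = 3
    out[al & ah & (n_active == 2)] = 2  # non-adjacent
    empty = n_active == 0
    if np.any(empty):
        arg = np.argmax(np.stack([mu_l, mu_m, mu_h]), axis=0)
        out[empty] = np.array([0, 2, 4], dtype=np.int8)[arg[empty]]
    return out


@dataclasses.dataclass(frozen=True)
class LabelMatrix:
    """Discretized dataset: label indices (into LABELS) per feature x sample."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    codes: np.ndarray  # int8, shape (n_features, n_samples)

    def label(self, i: int, j: int) -> str:
        return LABELS[self.codes[i, j]]


def discretize(
    ds: ExpressionDataset, model: MembershipModel, zeta: float
) -> LabelMatrix:
    """Element-wise fuzzy labeling of the whole matrix; shape is preserved."""
    if tuple(model.feature_ids) != tuple(ds.feature_ids):
        raise ValueError("membership model was not fitted on this dataset's features")
    z = (ds.values - model.centers[:, None]) / model.spreads[:, None]
    mu_m = np.exp(-0.5 * z * z)
    # evaluate through the family per-row only if a custom family is used
    if isinstance(model.family, GaussianSigmoidFamily):
        mu_h = 1.0 / (1.0 + np.exp(-2.0 * z))
        mu_l = 1.0 - mu_h
    else:
        mu_l = np.empty_like(ds.values)
        mu_m = np.empty_like(ds.values)
        mu_h = np.empty_like(ds.values)
        for i in range(ds.n_features):
            mu_l[i], mu_m[i], mu_h[i] = model.family.memberships(
                ds.values[i], model.centers[i], model.spreads[i]
            )
    codes = assign_labels(mu_l, mu_m, mu_h, zeta)
    return LabelMatrix(ds.feature_ids, ds.sample_ids, codes)


@dataclasses.dataclass(frozen=True)
class FuzzyPattern:
    """Per-class pattern: (feature, dominant label, within-class frequency)."""

    class_label: str
    entries: tuple[tuple[str, str, float], ...]

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def discover_fuzzy_patterns(
    labels: LabelMatrix, ds: ExpressionDataset, piVal: float
) -> list[FuzzyPattern]:
    """Find the fuzzy pattern of every class.

    For each class and feature, the dominant label is the most frequent
    label among the class's samples (ties broken by the fixed label order
    Low < Low-Medium < Medium < Medium-High < High); the feature enters the
    class pattern iff its frequency (dominant count / class size) >= piVal.
    Exactly one pattern per class is returned, in class order; an empty
    pattern logs a warning.
    """
    if not 0 < piVal <= 1:
        raise ValueError(f"piVal must be in (0, 1], got {piVal}")
    patterns: list[FuzzyPattern] = []
    class_cols = {}
    lab = np.array([ds.class_of[s] for s in labels.sample_ids], dtype=object)
    for cls in ds.classes:
        class_cols[cls] = np.flatnonzero(lab == cls)
    for cls in ds.classes:
        cols = class_cols[cls]
        sub = labels.codes[:, cols]
        # counts[l, g] = occurrences of label l for feature g within the class
        counts = np.stack([(sub == l).sum(axis=1) for l in range(len(LABELS))])
        dominant = counts.argmax(axis=0)  # argmax takes the first (lowest) label
        freq = counts.max(axis=0) / cols.size
        keep = np.flatnonzero(freq >= piVal)
        entries = tuple(
            (labels.feature_ids[g], LABELS[dominant[g]], float(freq[g])) for g in keep
        )
        if not entries:
            logger.warning(
                "fuzzy pattern for class %r is empty at piVal=%.3g", cls, piVal
            )
        patterns.append(FuzzyPattern(cls, entries))
    return patterns


def selected_features(patterns: Iterable[FuzzyPattern]) -> list[str]:
    """Union of all pattern features, first-appearance order over
    (class order, entry order)."""
    patterns = list(patterns)
    if not patterns:
        raise ValueError("no patterns given")
    seen: dict[str, None] = {}
    for p in patterns:
        for fid in p.feature_ids:
            seen.setdefault(fid, None)
    if not seen:
        raise ValidationError(
            "every fuzzy pattern is empty; relax piVal (smaller) or adjust zeta"
        )
    return list(seen)


# -- audit I/O ------------------------------------------------------------


def write_label_matrix(labels: LabelMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(labels.sample_ids) + "\n")
        for i, fid in enumerate(labels.feature_ids):
            row = "\t".join(LABELS[c] for c in labels.codes[i])
            fh.write(f"{fid}\t{row}\n")


def write_patterns(patterns: Iterable[FuzzyPattern], path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tfeature_id\tlabel\tfrequency\n")
        for p in patterns:
            for fid, lab, freq in p.entries:
                fh.write(f"{p.class_label}\t{fid}\t{lab}\t{freq:.12g}\n")


def read_patterns(path) -> list[FuzzyPattern]:
    """Read patterns written by :func:`write_patterns`, preserving order."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"class": str, "feature_id": str})
    patterns = []
    for cls in df["class"].drop_duplicates():
        sub = df[df["class"] == cls]
        entries = tuple(
            (str(r.feature_id), str(r.label), float(r.frequency))
            for r in sub.itertuples()
        )
        patterns.append(FuzzyPattern(str(cls), entries))
    return patterns
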