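"""Expression-matrix data model, readers/writers and validation.

The central container is :class:`ExpressionDataset`: a features x samples
matrix of continuous (log2-scale) expression values plus a class label per
sample.  Matrix orientation is fixed — features in rows, samples in columns;
a transposed file is detected only through header mismatch, never guessed.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ValidationError",
    "read_expression_matrix",
    "filter_low_variance",
    "write_ranked_list",
    "read_ranked_list",
]


class ValidationError(ValueError):
    """Raised when an input violates the dataset contract."""


@dataclasses.dataclass(frozen=True)
class ExpressionDataset:
    """A validated features x samples expression matrix with class labels.

    Parameters
    ----------
    feature_ids : sequence of unique feature identifiers (matrix rows).
    sample_ids : sequence of unique sample identifiers (matrix columns).
    values : float array of shape (n_features, n_samples); finite, no NaN.
    class_of : mapping sample_id -> class label covering every sample.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    class_of: Mapping[str, str]

    def __init__(self, feature_ids, sample_ids, values, class_of,
                 _min_class_size: int = 2):
        # _min_class_size=1 is used internally for train/test views, where a
        # held-out side may keep a single sample of a small class
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in sample_ids))
        object.__setattr__(
            self, "values", np.ascontiguousarray(values, dtype=np.float64)
        )
        object.__setattr__(self, "class_of", dict(class_of))
        self._validate(_min_class_size)

    def _validate(self, min_class_size: int = 2) -> None:
        n_feat, n_samp = len(self.feature_ids), len(self.sample_ids)
        if self.values.shape != (n_feat, n_samp):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n_feat} features x {n_samp} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = [k for k, c in Counter(ids).items() if c > 1]
            if dup:
                raise ValidationError(f"duplicate {name} id(s): {dup[:5]}")
        missing = [s for s in self.sample_ids if s not in self.class_of]
        if missing:
            raise ValidationError(
                f"sample(s) missing from the annotation: {missing[:5]}"
            )
        sizes = Counter(self.class_of[s] for s in self.sample_ids)
        if len(sizes) < 2:
            raise ValidationError("at least 2 classes are required")
        small = [c for c, n in sizes.items() if n < min_class_size]
        if small:
            raise ValidationError(
                f"class(es) with fewer than {min_class_size} samples: {small}"
            )

    # -- derived views ----------------------------------------------------

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct class labels in first-appearance order over samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.class_of[s], None)
        return tuple(seen)

    @property
    def labels(self) -> np.ndarray:
        """Per-sample class labels aligned with ``sample_ids``."""
        return np.array([self.class_of[s] for s in self.sample_ids], dtype=object)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def class_indices(self) -> dict[str, np.ndarray]:
        """Column indices of each class, keyed by label."""
        lab = self.labels
        return {c: np.flatnonzero(lab == c) for c in self.classes}

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        idx = [self.feature_index(f) for f in feature_ids]
        return ExpressionDataset(
            [self.feature_ids[i] for i in idx],
            self.sample_ids,
            self.values[idx, :],
            self.class_of,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None
        return ExpressionDataset(
            self.feature_ids,
            list(sample_ids),
            self.values[:, idx],
            {s: self.class_of[s] for s in sample_ids},
            _min_class_size=1,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_matrix(path, annotation_path) -> ExpressionDataset:
    """Read a TSV/CSV matrix (features in rows) and a sample annotation.

    The matrix header holds sample ids; the first column holds feature ids.
    The annotation is a two-column TSV/CSV mapping sample_id -> class label.
    Samples present in the matrix but absent from the annotation are an
    error; annotation rows for unknown samples are ignored.  Matrix column
    order is preserved.
    """
    path, annotation_path = Path(path), Path(annotation_path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    non_numeric = df.columns[
        ~df.apply(lambda col: pd.to_numeric(col, errors="coerce").notna().all())
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValidationError(
            f"malformed numeric cell in {path.name}: row {bad_rows[0]!r}, "
            f"column {col!r}"
        )
    ann = pd.read_csv(
        annotation_path,
        sep=_sniff_sep(annotation_path),
        dtype=str,
        comment="#",
    )
    if ann.shape[1] < 2:
        raise ValidationError(
            f"annotation {annotation_path.name} needs >=2 columns (sample, class)"
        )
    class_of = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))
    return ExpressionDataset(
        df.index.astype(str),
        df.columns.astype(str),
        df.to_numpy(dtype=np.float64),
        {s: class_of[s] for s in df.columns.astype(str) if s in class_of},
    )


def filter_low_variance(ds: ExpressionDataset, min_sd: float = 0.0) -> ExpressionDataset:
    """Drop features whose across-sample standard deviation is <= ``min_sd``.

    With the default ``min_sd=0`` only constant features are removed.  Order
    of surviving features is preserved; removing every feature is an error.
    """
    if min_sd < 0:
        raise ValueError("min_sd must be non-negative")
    sd = np.std(ds.values, axis=1, ddof=1)
    keep = np.flatnonzero(sd > min_sd)
    if keep.size == 0:
        raise ValidationError(
            f"min_sd={min_sd} removes every feature (max sd = {sd.max():.4g})"
        )
    if keep.size == ds.n_features:
        return ds
    return ExpressionDataset(
        [ds.feature_ids[i] for i in keep],
        ds.sample_ids,
        ds.values[keep, :],
        ds.class_of,
    )


def write_ranked_list(ranked, path) -> None:
    """Write a ranked feature list as TSV: rank (1-based), feature_id, importance."""
    entries = list(ranked)
    if not entries:
        raise ValueError("refusing to write an empty ranking")
    with open(path, "w") as fh:
        fh.write("rank\tfeature_id\timportance\n")
        for r, (fid, imp) in enumerate(entries, start=1):
            fh.write(f"{r}\t{fid}\t{imp:.12g}\n")


def read_ranked_list(path) -> list[tuple[str, float]]:
    """Read a ranking written by :func:`write_ranked_list`."""
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["feature_id"].astype(str), df["importance"].astype(float)))
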