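"""Synthetic multi-class expression matrices with planted class markers.

Emulates RMA-style log2 expression: i.i.d. Gaussian background noise with a
handful of features shifted in exactly one class each (a location model —
the fuzzy Low/Medium/High semantics are location-based, so mean shifts are
the natural planted signal).  Ground truth is returned so selection and
ranking can be scored against known markers.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .dataset import ExpressionDataset

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "standard_benchmark",
    "imbalanced_benchmark",
    "write_ground_truth",
]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    effect size ``delta`` is expressed in units of the noise sd ``sigma0``;
    ``directions`` optionally gives '+'/'-' per planted feature (default all
    up-shifts).  Planted sets are disjoint across classes.
    """

    n_classes: int = 4
    samples_per_class: tuple[int, ...] = (30, 30, 30, 30)
    n_features: int = 2000
    informative_per_class: int = 10
    delta: float = 2.0
    mu0: float = 7.0
    sigma0: float = 1.0
    directions: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "samples_per_class", tuple(int(n) for n in self.samples_per_class)
        )
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        if any(n < 2 for n in self.samples_per_class):
            raise ValueError("every class needs at least 2 samples")
        if self.informative_per_class * self.n_classes > self.n_features:
            raise ValueError("more planted features than features")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        n_planted = self.informative_per_class * self.n_classes
        if self.directions is not None:
            d = tuple(self.directions)
            if len(d) != n_planted or set(d) - {"+", "-"}:
                raise ValueError(
                    f"directions must be {n_planted} entries of '+'/'-'"
                )
            object.__setattr__(self, "directions", d)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """class label -> list of (feature_id, direction) planted in that class."""

    planted: Mapping[str, tuple[tuple[str, str], ...]]

    @property
    def all_features(self) -> list[str]:
        return [fid for entries in self.planted.values() for fid, _ in entries]


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset: Normal(mu0, sigma0^2) background, planted feature g
    of class c shifted by +/- delta*sigma0 in class-c samples only."""
    rng = np.random.default_rng(spec.seed)
    n_samples = sum(spec.samples_per_class)
    width = max(4, len(str(spec.n_features)))
    feature_ids = [f"G{i:0{width}d}" for i in range(1, spec.n_features + 1)]
    classes = [f"C{k + 1}" for k in range(spec.n_classes)]
    sample_ids, class_of = [], {}
    for cls, n_c in zip(classes, spec.samples_per_class):
        for j in range(1, n_c + 1):
            sid = f"{cls}_S{j:03d}"
            sample_ids.append(sid)
            class_of[sid] = cls
    values = rng.normal(spec.mu0, spec.sigma0, size=(spec.n_features, n_samples))
    # planted features: a seed-determined draw without replacement
    n_planted = spec.informative_per_class * spec.n_classes
    planted_rows = rng.choice(spec.n_features, size=n_planted, replace=False)
    directions = spec.directions or ("+",) * n_planted
    col_of_class = {}
    start = 0
    for cls, n_c in zip(classes, spec.samples_per_class):
        col_of_class[cls] = np.arange(start, start + n_c)
        start += n_c
    planted: dict[str, list[tuple[str, str]]] = {c: [] for c in classes}
    for j, row in enumerate(planted_rows):
        cls = classes[j // spec.informative_per_class]
        sign = 1.0 if directions[j] == "+" else -1.0
        values[row, col_of_class[cls]] += sign * spec.delta * spec.sigma0
        planted[cls].append((feature_ids[row], directions[j]))
    ds = ExpressionDataset(feature_ids, sample_ids, values, class_of)
    truth = GroundTruth({c: tuple(v) for c, v in planted.items()})
    return ds, truth


def standard_benchmark() -> tuple[ExpressionDataset, GroundTruth]:
    """The fixed balanced benchmark: 4 classes x 30 samples, 2000 features,
    10 planted per class, delta = 2, background N(7, 1), fixed seed."""
    return generate_dataset(
        SyntheticSpec(
            n_classes=4,
            samples_per_class=(30, 30, 30, 30),
            n_features=2000,
            informative_per_class=10,
            delta=2.0,
            mu0=7.0,
            sigma0=1.0,
            seed=20140923,
        )
    )


def imbalanced_benchmark() -> tuple[ExpressionDataset, GroundTruth]:
    """Imbalanced variant: 5 classes of 60/40/20/10/6 samples, otherwise as
    the standard benchmark."""
    return generate_dataset(
        SyntheticSpec(
            n_classes=5,
            samples_per_class=(60, 40, 20, 10, 6),
            n_features=2000,
            informative_per_class=10,
            delta=2.0,
            mu0=7.0,
            sigma0=1.0,
            seed=20140924,
        )
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tfeature_id\tdirection\n")
        for cls, entries in truth.planted.items():
            for fid, d in entries:
                fh.write(f"{cls}\t{fid}\t{d}\n")
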