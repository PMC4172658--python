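"""Run configuration for the FPRF pipeline.

All tunables of the two-step method live in one dataclass so a run is fully
described by (data, config, seed).  Values mirror the YAML config file; CLI
flags override both.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

DEFAULT_CUT_POINTS = (2, 3, 4, 5, 10, 20, 30, 50, 100, 150, 200, 250)


@dataclasses.dataclass
class FPConfig:
    """Parameters of fuzzy-pattern discovery, the ranking forest and the
    evaluation harness.

    zeta : activation threshold on membership values in (0, 1].
    piVal : minimum within-class frequency of the dominant fuzzy label for a
        feature to enter that class's fuzzy pattern, in (0, 1].  Small values
        give large, permissive patterns; the ranking forest is what separates
        signal from the extra noise features.
    ntree : trees in the ranking forest and the post-selection classifier.
    train_fraction : stratified train share of each evaluation split.
    n_boot : bootstrap iterations of the evaluation harness.
    cut_points : strictly increasing truncation lengths for the ranked list.
    alpha_split : stop splitting when the Bonferroni-adjusted split p-value
        exceeds this.  The default 1.0 follows the forest convention of
        unbiased-tree ensembles (no significance stop — trees split on the
        best candidate until purity or ``min_node``); set e.g. 0.05 for
        single-tree-style early stopping.
    min_node : minimum node size eligible for splitting.
    alpha_stability : family-wise level of the self-consistency test.
    min_sd : low-variance pre-filter threshold (0 drops only constant genes).
    seed : master seed; every stochastic stage derives its stream from it.
    """

    zeta: float = 0.5
    piVal: float = 0.5
    ntree: int = 1000
    train_fraction: float = 0.70
    n_boot: int = 30
    cut_points: tuple[int, ...] = DEFAULT_CUT_POINTS
    alpha_split: float = 1.0
    min_node: int = 5
    alpha_stability: float = 0.01
    min_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.zeta <= 1:
            raise ValueError(f"zeta must be in (0, 1], got {self.zeta}")
        if not 0 < self.piVal <= 1:
            raise ValueError(f"piVal must be in (0, 1], got {self.piVal}")
        if self.ntree < 1:
            raise ValueError("ntree must be a positive integer")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be a positive integer")
        cp = tuple(int(c) for c in self.cut_points)
        if any(c < 1 for c in cp) or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cut_points must be strictly increasing positive ints")
        self.cut_points = cp
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")
        if not 0 < self.alpha_split <= 1 or not 0 < self.alpha_stability <= 1:
            raise ValueError("alpha values must be in (0, 1]")
        if self.min_sd < 0:
            raise ValueError("min_sd must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "FPConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cut_points"] = list(d["cut_points"])
        return d

    def replace(self, **kw) -> "FPConfig":
        return dataclasses.replace(self, **kw)
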