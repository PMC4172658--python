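"""Bootstrap evaluation harness and selection-stability statistics.

The protocol: split the data into stratified train/test parts (70/30 by
default), run the feature selector on the training part only, fit a
post-selection classifier on the training part restricted to each n-top
feature list, score it on the test part, and repeat B times (30 by
default).  Alongside accuracy/F/G, the harness records the per-iteration
selected lists and tests which features recur across iterations more often
than a random-selection null predicts ("self-consistent" features); the
stability statistic is ns/tot — self-consistent over distinct selected.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import FPConfig
from .dataset import ExpressionDataset, filter_low_variance
from .forest import (
    RankedFeatureList,
    fit_fp_forest,
    fit_standard_forest,
    permutation_importance,
    predict as fp_predict,
    rank_features,
)
from .fuzzy import discover_fuzzy_patterns, discretize, fit_membership_model
from .metrics import accuracy, confusion_matrix, f_score, g_mean

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "StabilityResult",
    "stratified_split",
    "bootstrap_evaluate",
    "self_consistent_features",
    "stability_ratio",
    "fprf_selector",
    "unconstrained_rf_selector",
    "gini_rf_selector",
    "fixed_list_selector",
]

Selector = Callable[[ExpressionDataset, int], Sequence]


def stratified_split(
    ds: ExpressionDataset, train_fraction: float, rng: np.random.Generator
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified disjoint train/test split of the samples.

    Per class with N_c samples, round(train_fraction * N_c) go to train
    (round-half-up, clamped so each side keeps at least one sample of the
    class); sampling is without replacement.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    train_ids: list[str] = []
    test_ids: list[str] = []
    sample_ids = np.array(ds.sample_ids, dtype=object)
    for cls, idx in ds.class_indices().items():
        n_c = idx.size
        if n_c < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(np.floor(train_fraction * n_c + 0.5))
        n_train = min(max(n_train, 1), n_c - 1)
        perm = rng.permutation(n_c)
        train_ids.extend(sample_ids[idx[perm[:n_train]]])
        test_ids.extend(sample_ids[idx[perm[n_train:]]])
    # keep original sample order within each part for reproducible output
    order = {s: j for j, s in enumerate(ds.sample_ids)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return ds.subset_samples(train_ids), ds.subset_samples(test_ids)


# -- selectors -------------------------------------------------------------


def fprf_selector(config: FPConfig) -> Selector:
    """The two-step method as a harness selector.

    Fits membership functions on the training split, discovers fuzzy
    patterns, grows the FP-constrained forest and returns the permutation-
    importance ranking of the pattern-union features.
    """

    def select(train: ExpressionDataset, seed: int) -> RankedFeatureList:
        train = filter_low_variance(train, config.min_sd)
        model = fit_membership_model(train)
        labels = discretize(train, model, config.zeta)
        patterns = discover_fuzzy_patterns(labels, train, config.piVal)
        rng = np.random.default_rng(seed)
        forest = fit_fp_forest(train, patterns, config, rng)
        imp = permutation_importance(forest, train, rng)
        return rank_features(imp)

    return select


def unconstrained_rf_selector(config: FPConfig, mtry: int | None = None) -> Selector:
    """Baseline ablation: the same unbiased forest and OOB permutation
    importance, but with standard mtry node sampling (default 5) over *all*
    features — no fuzzy-pattern pre-selection or constraint."""

    def select(train: ExpressionDataset, seed: int) -> RankedFeatureList:
        rng = np.random.default_rng(seed)
        forest = fit_standard_forest(train, config, rng, mtry=mtry)
        imp = permutation_importance(forest, train, rng)
        return rank_features(imp)

    return select


def gini_rf_selector(config: FPConfig) -> Selector:
    """Alternative baseline: scikit-learn random forest ranked by impurity
    (Gini) importance.  Provided for external comparisons only — impurity
    importance is cardinality-biased and is not offered by the FP forest."""

    def select(train: ExpressionDataset, seed: int) -> RankedFeatureList:
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(
            n_estimators=config.ntree,
            max_features="sqrt",
            random_state=seed % (2**32),
            n_jobs=1,
        )
        clf.fit(train.values.T, train.labels.astype(str))
        imp = dict(zip(train.feature_ids, clf.feature_importances_.astype(float)))
        return rank_features(imp)

    return select


def fixed_list_selector(feature_lists: Sequence[Sequence[str]] | Sequence[str]) -> Selector:
    """Wrap externally produced feature lists (e.g. from another selection
    tool) as a harness selector; a flat list is reused on every iteration,
    a list of lists is consumed one per iteration."""
    state = {"i": 0}
    nested = bool(feature_lists) and not isinstance(feature_lists[0], str)

    def select(train: ExpressionDataset, seed: int):
        if nested:
            lst = list(feature_lists[state["i"] % len(feature_lists)])
            state["i"] += 1
        else:
            lst = list(feature_lists)
        return lst

    return select


# -- harness ---------------------------------------------------------------


@dataclasses.dataclass
class EvaluationResult:
    """Per-iteration, per-cut-point metrics plus the selected lists."""

    records: pd.DataFrame  # iteration, cut_point, n_features, acc, f, g
    selection_lists: list[list[str]]  # per-iteration ranked (or flat) lists
    failed_iterations: list[int]

    def summary(self) -> pd.DataFrame:
        """Mean and sd of each metric over iterations, per cut point."""
        return (
            self.records.groupby("cut_point")[["acc", "f", "g"]]
            .agg(["mean", "std"])
            .reset_index()
        )


def _post_selection_classifier(config: FPConfig, seed: int, fp_constrained: bool):
    if fp_constrained:
        return None  # handled inline (needs patterns on the reduced data)
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=config.ntree,
        max_features="sqrt",
        random_state=seed % (2**32),
        n_jobs=1,
    )


def bootstrap_evaluate(
    ds: ExpressionDataset,
    selector: Selector,
    config: FPConfig,
    rng: np.random.Generator | int | None = None,
    fp_constrained_classifier: bool = False,
) -> EvaluationResult:
    """Run the stratified-bootstrap evaluation protocol.

    For each of ``config.n_boot`` iterations: split, select on train only,
    then for every cut point fit the post-selection classifier (a standard
    random forest by default) on the truncated feature set and score the
    held-out part with accuracy, macro F and G-mean.  A selector returning
    a plain (unranked) list is scored once per iteration with cut_point 0.
    Per-iteration seeds derive from the master seed, so results are
    reproducible.
    """
    if rng is None:
        rng = config.seed
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rows = []
    lists: list[list[str]] = []
    failed: list[int] = []
    for b in range(1, config.n_boot + 1):
        split_rng = np.random.default_rng(rng.integers(2**31))
        sel_seed = int(rng.integers(2**31))
        clf_seed = int(rng.integers(2**31))
        train, test = stratified_split(ds, config.train_fraction, split_rng)
        selected = selector(train, sel_seed)
        ids = (
            selected.feature_ids
            if isinstance(selected, RankedFeatureList)
            else list(selected)
        )
        if not ids:
            logger.error("selector returned an empty list at iteration %d", b)
            failed.append(b)
            lists.append([])
            continue
        lists.append(list(ids))
        ranked = isinstance(selected, RankedFeatureList)
        cut_points = [c for c in config.cut_points if c <= len(ids)] if ranked else [0]
        if ranked and not cut_points:
            cut_points = [len(ids)]
        for cp in cut_points:
            feats = ids[:cp] if cp else ids
            rows.append(
                _score_once(
                    train, test, feats, config, clf_seed + cp,
                    fp_constrained_classifier, b, cp,
                )
            )
    records = pd.DataFrame(
        rows, columns=["iteration", "cut_point", "n_features", "acc", "f", "g"]
    )
    return EvaluationResult(records, lists, failed)


def _score_once(train, test, feats, config, seed, fp_constrained, iteration, cut_point):
    tr = train.subset_features(feats)
    te = test.subset_features(feats)
    if fp_constrained:
        model = fit_membership_model(filter_low_variance(tr, 0.0))
        flt = filter_low_variance(tr, 0.0)
        labels = discretize(flt, model, config.zeta)
        patterns = discover_fuzzy_patterns(labels, flt, config.piVal)
        forest = fit_fp_forest(flt, patterns, config, np.random.default_rng(seed % 2**31))
        y_pred = fp_predict(forest, te)
    else:
        clf = _post_selection_classifier(config, seed, False)
        clf.fit(tr.values.T, tr.labels.astype(str))
        y_pred = clf.predict(te.values.T)
    cm = confusion_matrix(te.labels, y_pred, train.classes)
    return (
        iteration,
        cut_point,
        len(feats),
        accuracy(cm),
        f_score(cm),
        g_mean(cm),
    )


# -- stability -------------------------------------------------------------


def _poisson_binomial_tail(probs: np.ndarray, s: int) -> float:
    """P(X >= s) for X a sum of independent Bernoulli(p_b) variables.

    Exact dynamic-programming convolution; B is small (tens) so cost is
    negligible.
    """
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= 1 - p
    return float(pmf[s:].sum())


def self_consistent_features(
    selection_lists: Sequence[Sequence[str]],
    n_universe: int,
    alpha: float = 0.01,
) -> set[str]:
    """Features selected more often than the random-selection null predicts.

    Null model: each iteration b picks its list of size m_b uniformly, so a
    given feature is included independently with probability p_b = m_b / P
    where P is the universe size.  A feature with selection count s is
    self-consistent iff the Poisson-binomial tail P(X >= s) (exact binomial
    when all list sizes agree) is at most alpha / P (Bonferroni over the
    universe).
    """
    lists = [list(l) for l in selection_lists]
    if len(lists) < 2:
        raise ValueError("need at least 2 selection lists")
    sizes = np.array([len(l) for l in lists])
    if np.any(sizes > n_universe):
        raise ValueError("a selection list is larger than the feature universe")
    counts: dict[str, int] = {}
    for l in lists:
        for fid in set(l):
            counts[fid] = counts.get(fid, 0) + 1
    probs = sizes / n_universe
    threshold = alpha / n_universe
    same_size = len(set(sizes.tolist())) == 1
    out = set()
    tail_cache: dict[int, float] = {}
    for fid, s in counts.items():
        if s not in tail_cache:
            if same_size:
                tail_cache[s] = float(
                    stats.binom.sf(s - 1, len(lists), probs[0])
                )
            else:
                tail_cache[s] = _poisson_binomial_tail(probs, s)
        if tail_cache[s] <= threshold:
            out.add(fid)
    return out


@dataclasses.dataclass(frozen=True)
class StabilityResult:
    """Self-consistency summary: ns stable of tot distinct selected features."""

    ns: int
    tot: int
    ratio: float
    selection_counts: Mapping[str, int]


def stability_ratio(
    selection_lists: Sequence[Sequence[str]], stable_set: set[str]
) -> StabilityResult:
    """ns / tot: self-consistent features over distinct selected features."""
    union: dict[str, int] = {}
    for l in selection_lists:
        for fid in set(l):
            union[fid] = union.get(fid, 0) + 1
    if not union:
        raise ValueError("no features were ever selected")
    extra = stable_set - set(union)
    if extra:
        raise ValueError(f"stable feature(s) never selected: {sorted(extra)[:5]}")
    ns, tot = len(stable_set), len(union)
    return StabilityResult(ns, tot, ns / tot, union)
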