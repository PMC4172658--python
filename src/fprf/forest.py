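"""Random forest of unbiased trees with fuzzy-pattern-constrained splits.

The node-splitting candidate set is not the usual ``mtry`` random features:
at every node one feature is drawn uniformly from each class's fuzzy pattern
and the union (deduplicated) forms the candidates, so the number of
candidates is at most the number of classes.  The split variable is chosen
by association strength — a one-way ANOVA F-test p-value of feature values
against node class labels, Bonferroni-adjusted over the candidates — rather
than impurity gain, which avoids the cardinality bias of Gini-style
selection; Gini importance is deliberately not offered.  Features are
ranked by permutation accuracy importance on out-of-bag (OOB) samples.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .config import FPConfig
from .dataset import ExpressionDataset
from .fuzzy import FuzzyPattern, selected_features

__all__ = [
    "Tree",
    "FPForest",
    "RankedFeatureList",
    "draw_node_candidates",
    "grow_tree",
    "fit_fp_forest",
    "fit_standard_forest",
    "predict",
    "oob_error",
    "permutation_importance",
    "rank_features",
    "top_n",
    "save_forest",
    "load_forest",
]

FOREST_FORMAT_VERSION = 1


@dataclasses.dataclass
class Tree:
    """Array-encoded binary classification tree.

    ``feature[i] >= 0`` marks an internal node with split
    ``x[feature[i]] <= threshold[i]`` sending a sample left; ``feature[i] == -1``
    marks a leaf predicting ``leaf_pred[i]``.  ``counts[i]`` are the training
    class counts of the node (leaf vote vector).
    """

    feature: np.ndarray  # int32
    threshold: np.ndarray  # float64
    left: np.ndarray  # int32
    right: np.ndarray  # int32
    leaf_pred: np.ndarray  # int32, -1 on internal nodes
    counts: np.ndarray  # int64, (n_nodes, n_classes)

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Class codes for a samples x features matrix."""
        node = np.zeros(X.shape[0], dtype=np.int32)
        while True:
            feat = self.feature[node]
            active = np.flatnonzero(feat >= 0)
            if active.size == 0:
                return self.leaf_pred[node]
            cur = node[active]
            go_left = X[active, feat[active]] <= self.threshold[cur]
            node[active] = np.where(go_left, self.left[cur], self.right[cur])

    def used_features(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])


class _TreeBuilder:
    def __init__(self, n_classes: int):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.leaf_pred: list[int] = []
        self.counts: list[np.ndarray] = []
        self.n_classes = n_classes

    def add(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.leaf_pred.append(-1)
        self.counts.append(np.zeros(self.n_classes, dtype=np.int64))
        return len(self.feature) - 1

    def finish(self) -> Tree:
        return Tree(
            np.asarray(self.feature, dtype=np.int32),
            np.asarray(self.threshold, dtype=np.float64),
            np.asarray(self.left, dtype=np.int32),
            np.asarray(self.right, dtype=np.int32),
            np.asarray(self.leaf_pred, dtype=np.int32),
            np.vstack(self.counts),
        )


def draw_node_candidates(
    patterns: Sequence[FuzzyPattern], rng: np.random.Generator
) -> list[str]:
    """One feature uniformly at random from each non-empty pattern, deduplicated.

    The result has at most one entry per class; empty patterns are skipped
    and an all-empty pattern list is an error.
    """
    picks: dict[str, None] = {}
    any_nonempty = False
    for p in patterns:
        if len(p) == 0:
            continue
        any_nonempty = True
        picks.setdefault(p.feature_ids[int(rng.integers(len(p)))], None)
    if not any_nonempty:
        raise ValueError("all fuzzy patterns are empty; nothing to sample")
    return list(picks)


def _draw_candidate_cols(
    fp_cols: Sequence[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Index-level candidate draw used inside tree growth."""
    picks: dict[int, None] = {}
    for cols in fp_cols:
        if cols.size:
            picks.setdefault(int(cols[int(rng.integers(cols.size))]), None)
    return np.fromiter(picks, dtype=np.int64)


def _anova_p(x: np.ndarray, y: np.ndarray, n_classes: int) -> float:
    """One-way ANOVA F-test p-value of x grouped by class code y.

    Returns 1.0 when the statistic is undefined (constant x or no residual
    degrees of freedom) and 0.0 for a perfect within-group fit.
    """
    return float(_anova_p_columns(x[:, None], y, n_classes)[0])


def _anova_p_columns(Xsub: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """Vectorized one-way ANOVA p-values, one per column of ``Xsub``."""
    n, m = Xsub.shape
    member = np.zeros((n_classes, n))
    member[y, np.arange(n)] = 1.0
    cnt = member.sum(axis=1)
    present = cnt > 0
    k = int(present.sum())
    if k < 2 or n - k < 1:
        return np.ones(m)
    Xc = Xsub - Xsub.mean(axis=0)  # center to dodge cancellation at large means
    gsum = member[present] @ Xc
    gmean = gsum / cnt[present, None]
    ssb = (cnt[present, None] * gmean**2).sum(axis=0)
    sst = (Xc**2).sum(axis=0)
    ssw = np.maximum(sst - ssb, 0.0)
    p = np.ones(m)
    defined = ssb > 1e-12 * np.maximum(sst, 1.0)
    perfect = defined & (ssw <= 1e-12 * np.maximum(sst, 1.0))
    p[perfect] = 0.0
    rest = defined & ~perfect
    if rest.any():
        f = (ssb[rest] / (k - 1)) / (ssw[rest] / (n - k))
        p[rest] = stats.f.sf(f, k - 1, n - k)
    return p


def _best_threshold(x: np.ndarray, y: np.ndarray, n_classes: int):
    """Midpoint threshold maximizing the 2 x k chi-squared association of the
    induced partition with the class labels; None when x is constant."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = xs.size
    boundary = np.flatnonzero(xs[:-1] < xs[1:])  # split after position i
    if boundary.size == 0:
        return None
    onehot = np.zeros((n, n_classes), dtype=np.float64)
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    present = total > 0
    n_left = (boundary + 1).astype(np.float64)
    c_left = cum[boundary][:, present]
    tot = total[present]
    c_right = tot[None, :] - c_left
    e_left = n_left[:, None] * tot[None, :] / n
    e_right = (n - n_left)[:, None] * tot[None, :] / n
    chi2 = ((c_left - e_left) ** 2 / e_left).sum(axis=1) + (
        (c_right - e_right) ** 2 / e_right
    ).sum(axis=1)
    best = int(np.argmax(chi2))  # ties -> smallest threshold
    i = boundary[best]
    return 0.5 * (xs[i] + xs[i + 1])


def _grow_tree_arrays(
    X: np.ndarray,
    y: np.ndarray,
    sample_idx: np.ndarray,
    draw_candidates: Callable[[np.random.Generator], np.ndarray],
    n_classes: int,
    alpha_split: float,
    min_node: int,
    rng: np.random.Generator,
) -> Tree:
    tb = _TreeBuilder(n_classes)
    root = tb.add()
    stack = [(root, sample_idx)]
    while stack:
        node, idx = stack.pop()
        yk = y[idx]
        counts = np.bincount(yk, minlength=n_classes).astype(np.int64)
        tb.counts[node] = counts
        tb.leaf_pred[node] = int(np.argmax(counts))  # ties -> class order
        if idx.size < min_node or np.count_nonzero(counts) < 2:
            continue
        cand = draw_candidates(rng)
        if cand.size == 0:
            continue
        pvals = _anova_p_columns(X[np.ix_(idx, cand)], yk, n_classes)
        best = int(np.argmin(pvals))  # ties -> draw order
        p_adj = min(1.0, pvals[best] * cand.size)
        if p_adj > alpha_split:
            continue
        thr = _best_threshold(X[idx, cand[best]], yk, n_classes)
        if thr is None:
            continue
        go_left = X[idx, cand[best]] <= thr
        left_idx, right_idx = idx[go_left], idx[~go_left]
        if left_idx.size == 0 or right_idx.size == 0:
            continue
        tb.feature[node] = int(cand[best])
        tb.threshold[node] = float(thr)
        tb.leaf_pred[node] = -1
        lid, rid = tb.add(), tb.add()
        tb.left[node], tb.right[node] = lid, rid
        stack.append((rid, right_idx))
        stack.append((lid, left_idx))
    return tb.finish()


@dataclasses.dataclass
class FPForest:
    """Ensemble of FP-constrained trees with OOB bookkeeping.

    ``feature_ids`` fixes the column order of the internal matrix; every
    split feature of every tree belongs to the union of the pattern features.
    """

    trees: list[Tree]
    feature_ids: tuple[str, ...]
    classes: tuple[str, ...]
    patterns: list[FuzzyPattern]
    in_bag: list[np.ndarray]  # per-tree bootstrap index multiset
    oob: list[np.ndarray]  # per-tree out-of-bag sample indices
    seed: int

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def _matrix_from(self, ds: ExpressionDataset) -> np.ndarray:
        cols = []
        for fid in self.feature_ids:
            try:
                cols.append(ds.feature_index(fid))
            except KeyError:
                raise KeyError(f"input is missing feature {fid!r}") from None
        return ds.values[cols, :].T.copy()


def grow_tree(
    train: ExpressionDataset,
    patterns: Sequence[FuzzyPattern],
    config: FPConfig,
    rng: np.random.Generator,
) -> tuple[Tree, tuple[str, ...]]:
    """Grow a single tree on the full training set (no bootstrap).

    Returns the tree and the feature-id tuple defining its column order.
    Exposed mainly for inspection and testing; forests are built with
    :func:`fit_fp_forest`.
    """
    feats = selected_features(patterns)
    sub = train.subset_features(feats)
    X = sub.values.T.copy()
    col = {f: i for i, f in enumerate(feats)}
    fp_cols = [
        np.array([col[f] for f in p.feature_ids], dtype=np.int64) for p in patterns
    ]
    classes = train.classes
    cls_code = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_code[c] for c in train.labels], dtype=np.int64)
    tree = _grow_tree_arrays(
        X,
        y,
        np.arange(train.n_samples),
        lambda r: _draw_candidate_cols(fp_cols, r),
        len(classes),
        config.alpha_split,
        config.min_node,
        rng,
    )
    return tree, tuple(feats)


def fit_fp_forest(
    train: ExpressionDataset,
    patterns: Sequence[FuzzyPattern],
    config: FPConfig,
    rng: np.random.Generator | int | None = None,
) -> FPForest:
    """Fit ``config.ntree`` trees, each on an independent bootstrap (with
    replacement) of the training samples; fully deterministic given the seed."""
    if rng is None:
        rng = config.seed
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    feats = selected_features(patterns)
    missing = set(feats) - set(train.feature_ids)
    if missing:
        raise KeyError(f"pattern feature(s) absent from training data: {sorted(missing)[:5]}")
    sub = train.subset_features(feats)
    X = np.ascontiguousarray(sub.values.T)
    col = {f: i for i, f in enumerate(feats)}
    fp_cols = [
        np.array([col[f] for f in p.feature_ids], dtype=np.int64) for p in patterns
    ]
    classes = train.classes
    cls_code = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_code[c] for c in train.labels], dtype=np.int64)
    return _fit_forest(
        X, y, config, rng,
        lambda r: _draw_candidate_cols(fp_cols, r),
        tuple(feats), classes, list(patterns),
        seed if seed is not None else -1,
    )


def _fit_forest(X, y, config, rng, draw_candidates, feats, classes, patterns, seed):
    n = X.shape[0]
    trees, in_bags, oobs = [], [], []
    for _ in range(config.ntree):
        in_bag = rng.integers(0, n, size=n)
        mask = np.zeros(n, dtype=bool)
        mask[in_bag] = True
        oob = np.flatnonzero(~mask)
        tree = _grow_tree_arrays(
            X, y, in_bag, draw_candidates, len(classes),
            config.alpha_split, config.min_node, rng,
        )
        trees.append(tree)
        in_bags.append(in_bag)
        oobs.append(oob)
    return FPForest(trees, feats, classes, patterns, in_bags, oobs, seed)


def fit_standard_forest(
    train: ExpressionDataset,
    config: FPConfig,
    rng: np.random.Generator | int | None = None,
    mtry: int | None = None,
) -> FPForest:
    """Fit the same unbiased forest with *standard* node sampling.

    Candidates at each node are ``mtry`` features (default 5, the unbiased-
    forest convention) drawn without replacement from all features — the
    conventional random forest rule the FP-constrained draw replaces,
    exposed so the two samplers can be compared with everything else held
    fixed.  The returned forest has an empty pattern list.
    """
    if rng is None:
        rng = config.seed
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    m = train.n_features
    if mtry is None:
        mtry = 5
    mtry = min(max(mtry, 1), m)
    X = np.ascontiguousarray(train.values.T)
    classes = train.classes
    cls_code = {c: i for i, c in enumerate(classes)}
    y = np.array([cls_code[c] for c in train.labels], dtype=np.int64)
    return _fit_forest(
        X, y, config, rng,
        lambda r: r.choice(m, size=mtry, replace=False),
        tuple(train.feature_ids), classes, [],
        seed if seed is not None else -1,
    )


def predict(forest: FPForest, ds: ExpressionDataset) -> np.ndarray:
    """Majority-vote class labels for the samples of ``ds``.

    Vote ties are broken by class order.  ``ds`` must carry every feature the
    forest was built on; a missing feature raises an error naming it.
    """
    X = forest._matrix_from(ds)
    votes = np.zeros((X.shape[0], len(forest.classes)), dtype=np.int64)
    rows = np.arange(X.shape[0])
    for tree in forest.trees:
        votes[rows, tree.predict_codes(X)] += 1
    return np.array(forest.classes, dtype=object)[votes.argmax(axis=1)]


def oob_error(forest: FPForest, train: ExpressionDataset) -> float:
    """Out-of-bag misclassification rate of the forest on its training data."""
    X = forest._matrix_from(train)
    cls_code = {c: i for i, c in enumerate(forest.classes)}
    y = np.array([cls_code[c] for c in train.labels], dtype=np.int64)
    votes = np.zeros((X.shape[0], len(forest.classes)), dtype=np.int64)
    for tree, oob in zip(forest.trees, forest.oob):
        if oob.size == 0:
            continue
        votes[oob, tree.predict_codes(X[oob])] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        return float("nan")
    pred = votes.argmax(axis=1)
    return float(np.mean(pred[covered] != y[covered]))


def permutation_importance(
    forest: FPForest,
    train: ExpressionDataset,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """OOB permutation accuracy importance per selected feature.

    For every tree with a non-empty OOB set, the OOB accuracy is compared
    with the accuracy after permuting one feature's values across the tree's
    OOB samples (one fresh permutation per tree/feature pair).  A feature's
    importance is the mean accuracy drop over those trees; features a tree
    does not split on contribute exactly zero for that tree, and features
    used by no tree have importance exactly 0.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))
    X = forest._matrix_from(train)
    cls_code = {c: i for i, c in enumerate(forest.classes)}
    y = np.array([cls_code[c] for c in train.labels], dtype=np.int64)
    m = len(forest.feature_ids)
    drop_sum = np.zeros(m, dtype=np.float64)
    n_oob_trees = 0
    for tree, oob in zip(forest.trees, forest.oob):
        if oob.size == 0:
            continue
        n_oob_trees += 1
        sub = X[oob].copy()
        y_oob = y[oob]
        base_acc = np.mean(tree.predict_codes(sub) == y_oob)
        for g in tree.used_features():
            saved = sub[:, g].copy()
            sub[:, g] = saved[rng.permutation(oob.size)]
            perm_acc = np.mean(tree.predict_codes(sub) == y_oob)
            sub[:, g] = saved
            drop_sum[g] += base_acc - perm_acc
    if n_oob_trees == 0:
        return {fid: 0.0 for fid in forest.feature_ids}
    return {
        fid: float(drop_sum[i] / n_oob_trees)
        for i, fid in enumerate(forest.feature_ids)
    }


class RankedFeatureList(list):
    """(feature_id, importance) pairs, importance-descending, ties by id."""

    @property
    def feature_ids(self) -> list[str]:
        return [fid for fid, _ in self]


def rank_features(importance: Mapping[str, float]) -> RankedFeatureList:
    """Sort an importance map: descending importance, ties lexicographic by id."""
    if not importance:
        raise ValueError("empty importance map")
    return RankedFeatureList(
        sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    )


def top_n(ranked: Sequence, n: int) -> list[str]:
    """First ``n`` feature ids of a ranking (all of them when n exceeds it)."""
    import logging

    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranked):
        logging.getLogger(__name__).warning(
            "requested top-%d of a %d-entry ranking; returning all", n, len(ranked)
        )
    return [fid for fid, _ in list(ranked)[:n]]


# -- serialization --------------------------------------------------------


def save_forest(forest: FPForest, path) -> None:
    """Serialize a forest to a versioned JSON file (text, reloadable)."""
    doc = {
        "format_version": FOREST_FORMAT_VERSION,
        "feature_ids": list(forest.feature_ids),
        "classes": list(forest.classes),
        "seed": forest.seed,
        "patterns": [
            {"class": p.class_label, "entries": [list(e) for e in p.entries]}
            for p in forest.patterns
        ],
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "leaf_pred": t.leaf_pred.tolist(),
                "counts": t.counts.tolist(),
            }
            for t in forest.trees
        ],
        "in_bag": [b.tolist() for b in forest.in_bag],
        "oob": [o.tolist() for o in forest.oob],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_forest(path) -> FPForest:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FOREST_FORMAT_VERSION:
        raise ValueError(
            f"unsupported forest format version {doc.get('format_version')!r}"
        )
    trees = [
        Tree(
            np.asarray(t["feature"], dtype=np.int32),
            np.asarray(t["threshold"], dtype=np.float64),
            np.asarray(t["left"], dtype=np.int32),
            np.asarray(t["right"], dtype=np.int32),
            np.asarray(t["leaf_pred"], dtype=np.int32),
            np.asarray(t["counts"], dtype=np.int64),
        )
        for t in doc["trees"]
    ]
    patterns = [
        FuzzyPattern(p["class"], tuple((e[0], e[1], float(e[2])) for e in p["entries"]))
        for p in doc["patterns"]
    ]
    return FPForest(
        trees,
        tuple(doc["feature_ids"]),
        tuple(doc["classes"]),
        patterns,
        [np.asarray(b, dtype=np.int64) for b in doc["in_bag"]],
        [np.asarray(o, dtype=np.int64) for o in doc["oob"]],
        int(doc["seed"]),
    )
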