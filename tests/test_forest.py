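import numpy as np
import pytest
from scipy import stats

from fprf import (
    FPConfig,
    FuzzyPattern,
    draw_node_candidates,
    filter_low_variance,
    discover_fuzzy_patterns,
    discretize,
    fit_fp_forest,
    fit_membership_model,
    fit_standard_forest,
    grow_tree,
    load_forest,
    permutation_importance,
    predict,
    rank_features,
    save_forest,
    top_n,
)
from fprf.forest import _anova_p_columns
from fprf.synthetic import SyntheticSpec, generate_dataset


def fp(cls, *fids):
    return FuzzyPattern(cls, tuple((f, "High", 1.0) for f in fids))


def two_class_ds(make_ds, rng, n_per=10, n_feat=3, effect=3.0):
    vals = rng.normal(0, 1, size=(n_feat, 2 * n_per))
    vals[0, n_per:] += effect  # g1 separates the classes
    return make_ds(vals, ["A"] * n_per + ["B"] * n_per)


class TestDrawNodeCandidates:
    def test_singleton_patterns_always_all_selected(self):
        rng = np.random.default_rng(0)
        pats = [fp("A", "g1"), fp("B", "g2"), fp("C", "g3")]
        for _ in range(20):
            assert set(draw_node_candidates(pats, rng)) == {"g1", "g2", "g3"}

    def test_shared_feature_deduplicated(self):
        rng = np.random.default_rng(0)
        assert draw_node_candidates([fp("A", "g1"), fp("B", "g1")], rng) == ["g1"]

    def test_empty_patterns_skipped_and_all_empty_errors(self):
        rng = np.random.default_rng(0)
        pats = [FuzzyPattern("A", ()), fp("B", "g2")]
        assert draw_node_candidates(pats, rng) == ["g2"]
        with pytest.raises(ValueError):
            draw_node_candidates([FuzzyPattern("A", ())], rng)

    def test_within_pattern_uniformity(self):
        # 10 000 draws from a 4-entry pattern: each member within 3 sigma
        # of 2500 under the multinomial
        rng = np.random.default_rng(123)
        pat = fp("A", "g1", "g2", "g3", "g4")
        counts = {f: 0 for f in pat.feature_ids}
        for _ in range(10_000):
            counts[draw_node_candidates([pat], rng)[0]] += 1
        sigma = np.sqrt(10_000 * 0.25 * 0.75)
        for f in counts:
            assert abs(counts[f] - 2500) <= 3 * sigma


class TestGrowTree:
    def test_pure_node_is_a_leaf(self, make_ds):
        # on a perfectly separable feature each side of the first split is
        # pure and must terminate as a leaf immediately
        rng = np.random.default_rng(0)
        ds = two_class_ds(make_ds, rng, effect=10.0)
        tree, feats = grow_tree(ds, [fp("A", "g1"), fp("B", "g1")],
                                FPConfig(), rng)
        assert tree.feature[0] == 0
        left, right = tree.left[0], tree.right[0]
        assert tree.feature[left] == -1 and tree.feature[right] == -1

    def test_perfect_separator_single_split(self, make_ds):
        rng = np.random.default_rng(1)
        ds = two_class_ds(make_ds, rng, effect=10.0)
        tree, feats = grow_tree(ds, [fp("A", "g1"), fp("B", "g1")],
                                FPConfig(), rng)
        a_max = ds.values[0, :10].max()
        b_min = ds.values[0, 10:].min()
        assert a_max < tree.threshold[0] < b_min
        counts_left = tree.counts[tree.left[0]]
        counts_right = tree.counts[tree.right[0]]
        assert np.count_nonzero(counts_left) == 1
        assert np.count_nonzero(counts_right) == 1

    def test_split_variable_matches_exhaustive_scan(self, make_ds):
        # singleton patterns make the candidate set deterministic, so the
        # chosen root split variable must match a brute-force scan
        # minimizing the one-way ANOVA p-value over the candidates
        rng = np.random.default_rng(42)
        for rep in range(10):
            vals = rng.normal(0, 1, size=(3, 21))
            groups = [slice(0, 7), slice(7, 14), slice(14, 21)]
            vals[rep % 3, groups[rep % 3]] += 1.5
            ds = make_ds(vals, ["A"] * 7 + ["B"] * 7 + ["C"] * 7)
            pats = [fp("A", "g1"), fp("B", "g2"), fp("C", "g3")]
            tree, feats = grow_tree(ds, pats, FPConfig(), np.random.default_rng(rep))
            assert tree.feature[0] >= 0
            pvals = [
                stats.f_oneway(v[groups[0]], v[groups[1]], v[groups[2]]).pvalue
                for v in ds.values
            ]
            assert feats[tree.feature[0]] == ds.feature_ids[int(np.argmin(pvals))]


class TestFitForest:
    def test_single_tree_oob_complements_bootstrap(self, make_ds):
        rng = np.random.default_rng(3)
        ds = two_class_ds(make_ds, rng)
        forest = fit_fp_forest(ds, [fp("A", "g1"), fp("B", "g2")],
                               FPConfig(ntree=1), rng)
        in_bag = set(forest.in_bag[0].tolist())
        oob = set(forest.oob[0].tolist())
        assert in_bag | oob == set(range(ds.n_samples))
        assert in_bag & oob == set()
        assert len(forest.in_bag[0]) == ds.n_samples  # with-replacement multiset

    def test_seed_determinism(self, make_ds):
        rng = np.random.default_rng(9)
        ds = two_class_ds(make_ds, rng)
        pats = [fp("A", "g1", "g2"), fp("B", "g2", "g3")]
        cfg = FPConfig(ntree=20)
        f1 = fit_fp_forest(ds, pats, cfg, np.random.default_rng(5))
        f2 = fit_fp_forest(ds, pats, cfg, np.random.default_rng(5))
        assert all(
            np.array_equal(t1.feature, t2.feature)
            and np.allclose(t1.threshold, t2.threshold, equal_nan=True)
            for t1, t2 in zip(f1.trees, f2.trees)
        )
        np.testing.assert_array_equal(predict(f1, ds), predict(f2, ds))
        i1 = permutation_importance(f1, ds, np.random.default_rng(11))
        i2 = permutation_importance(f2, ds, np.random.default_rng(11))
        assert i1 == i2

    def test_oob_fraction_near_exp_minus_one(self, make_ds):
        rng = np.random.default_rng(4)
        n = 100
        vals = rng.normal(0, 1, size=(2, n))
        vals[0, n // 2:] += 3
        ds = make_ds(vals, ["A"] * (n // 2) + ["B"] * (n // 2))
        forest = fit_fp_forest(ds, [fp("A", "g1"), fp("B", "g2")],
                               FPConfig(ntree=200), rng)
        fracs = [o.size / n for o in forest.oob]
        expect = (1 - 1 / n) ** n
        se = np.sqrt(expect * (1 - expect) / n / 200)
        assert abs(np.mean(fracs) - expect) < 3 * se

    def test_split_features_stay_inside_pattern_union(self, make_ds):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(6, 30))
        vals[0, 15:] += 2
        ds = make_ds(vals, ["A"] * 15 + ["B"] * 15)
        pats = [fp("A", "g1", "g2"), fp("B", "g3")]
        forest = fit_fp_forest(ds, pats, FPConfig(ntree=50), rng)
        union_cols = {forest.feature_ids.index(f) for f in ("g1", "g2", "g3")}
        for tree in forest.trees:
            assert set(tree.used_features().tolist()) <= union_cols


class TestPredict:
    def test_majority_vote_and_sample_order_invariance(self, make_ds):
        rng = np.random.default_rng(8)
        ds = two_class_ds(make_ds, rng)
        forest = fit_fp_forest(ds, [fp("A", "g1"), fp("B", "g1")],
                               FPConfig(ntree=25), rng)
        pred = predict(forest, ds)
        rev = ds.subset_samples(list(ds.sample_ids)[::-1])
        pred_rev = predict(forest, rev)
        np.testing.assert_array_equal(pred[::-1], pred_rev)

    def test_separable_training_accuracy_is_one(self, make_ds):
        rng = np.random.default_rng(10)
        ds = two_class_ds(make_ds, rng, n_per=15, effect=3.0)
        forest = fit_fp_forest(ds, [fp("A", "g1"), fp("B", "g1")],
                               FPConfig(ntree=100), rng)
        assert np.mean(predict(forest, ds) == ds.labels) == 1.0

    def test_missing_feature_is_named(self, make_ds):
        rng = np.random.default_rng(11)
        ds = two_class_ds(make_ds, rng)
        forest = fit_fp_forest(ds, [fp("A", "g1"), fp("B", "g2")],
                               FPConfig(ntree=5), rng)
        other = ds.subset_features(["g2", "g3"])
        with pytest.raises(KeyError, match="g1"):
            predict(forest, other)


class TestPermutationImportance:
    def test_unused_feature_importance_exactly_zero(self, make_ds):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, size=(3, 20))
        vals[0, 10:] += 8  # g1 dominates; g3 is in no pattern entry used
        ds = make_ds(vals, ["A"] * 10 + ["B"] * 10)
        forest = fit_fp_forest(ds, [fp("A", "g1"), fp("B", "g1")],
                               FPConfig(ntree=30), rng)
        imp = permutation_importance(forest, ds, rng)
        assert set(imp) == {"g1"}
        # constant feature in a pattern: never splittable -> importance 0
        vals2 = vals.copy()
        vals2[2, :] = 4.2
        ds2 = make_ds(vals2, ["A"] * 10 + ["B"] * 10)
        forest2 = fit_fp_forest(ds2, [fp("A", "g1"), fp("B", "g3")],
                                FPConfig(ntree=30), rng)
        imp2 = permutation_importance(forest2, ds2, rng)
        assert imp2["g3"] == 0.0

    def test_planted_feature_ranks_first(self, make_ds):
        # single planted marker per class among 49 noise features
        # (effect 2.5 sd, 2 classes x 25): a planted feature tops the
        # ranking in >= 95 of 100 seeded runs
        cfg = FPConfig(ntree=150)
        hits = 0
        for seed in range(100):
            spec = SyntheticSpec(
                n_classes=2, samples_per_class=(25, 25), n_features=51,
                informative_per_class=1, delta=2.5, seed=1000 + seed,
            )
            ds, truth = generate_dataset(spec)
            ds = filter_low_variance(ds, 0.0)
            model = fit_membership_model(ds)
            labels = discretize(ds, model, cfg.zeta)
            pats = discover_fuzzy_patterns(labels, ds, cfg.piVal)
            rng = np.random.default_rng(seed)
            forest = fit_fp_forest(ds, pats, cfg, rng)
            ranked = rank_features(permutation_importance(forest, ds, rng))
            if ranked[0][0] in set(truth.all_features):
                hits += 1
        assert hits >= 95


class TestRanking:
    def test_rank_and_tie_break(self):
        ranked = rank_features({"a": 0.1, "b": 0.3, "c": 0.1})
        assert ranked.feature_ids == ["b", "a", "c"]
        assert sorted(ranked.feature_ids) == ["a", "b", "c"]  # permutation

    def test_top_n_caps_at_length(self):
        ranked = rank_features({"a": 0.1, "b": 0.3})
        assert top_n(ranked, 1) == ["b"]
        assert top_n(ranked, 10) == ["b", "a"]
        assert top_n(ranked, len(ranked)) == ranked.feature_ids


class TestUnbiasedSplitSelection:
    def test_cardinality_does_not_bias_selection(self):
        # pure noise, one 2-valued and one 32-valued candidate: over 500
        # root nodes the 2-valued feature should win about half the time
        rng = np.random.default_rng(42)
        n, wins2, contested = 64, 0, 0
        for _ in range(500):
            y = rng.integers(0, 2, n)
            a = rng.integers(0, 2, n).astype(float)
            b = rng.integers(0, 32, n).astype(float)
            p = _anova_p_columns(np.column_stack([a, b]), y, 2)
            if p[0] == p[1]:
                continue
            contested += 1
            wins2 += int(p[0] < p[1])
        pval = stats.binomtest(wins2, contested, 0.5).pvalue
        assert pval > 0.001


class TestSerialization:
    def test_save_load_round_trip(self, make_ds, tmp_path):
        rng = np.random.default_rng(13)
        ds = two_class_ds(make_ds, rng)
        forest = fit_fp_forest(ds, [fp("A", "g1"), fp("B", "g2")],
                               FPConfig(ntree=10), rng)
        path = tmp_path / "forest.json"
        save_forest(forest, path)
        loaded = load_forest(path)
        np.testing.assert_array_equal(predict(forest, ds), predict(loaded, ds))
        assert loaded.feature_ids == forest.feature_ids
        assert loaded.classes == forest.classes
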