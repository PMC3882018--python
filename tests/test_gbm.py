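"""Boosted regression trees: split search, tree growth, boosting loop, VIM."""

import numpy as np
import pytest
from scipy.stats import rankdata

from boostfilter.gbm import (BoostedTreeRegressor, best_split, fit_gbm,
                             fit_tree, gbm_rank)


def split_oracle(G, resid, members, min_node):
    """Exhaustive search over all P variables x 2 split points, computing
    daughter SSEs directly (independent of the histogram path)."""
    members = np.asarray(members)
    best = (-1, np.nan, 0.0)
    parent = resid[members]
    sse_parent = np.sum((parent - parent.mean()) ** 2)
    for j in range(G.shape[1]):
        for thr in (0.5, 1.5):
            left = members[G[members, j] < thr]
            right = members[G[members, j] >= thr]
            if len(left) < min_node or len(right) < min_node:
                continue
            sse = sum(np.sum((resid[s] - resid[s].mean()) ** 2)
                      for s in (left, right))
            imp = sse_parent - sse
            if imp > best[2]:
                best = (j, thr, imp)
    return best


class TestBestSplit:
    def test_only_informative_variable_selected(self, rng):
        G = np.column_stack([rng.integers(0, 3, 100),
                             np.ones(100), np.full(100, 2.0)])
        resid = 0.7 * G[:, 0]
        j, thr, imp = best_split(resid, np.arange(100), G)
        assert j == 0
        assert imp > 0

    def test_small_fixture_matches_brute_force(self):
        G = np.array([[0, 2], [1, 0], [2, 1], [1, 2], [0, 0],
                      [2, 2], [0, 1], [1, 1], [2, 0], [0, 2]], dtype=float)
        resid = np.array([0.3, -1.2, 2.1, 0.4, -0.5, 1.8, -0.2, 0.1,
                          1.5, -0.9])
        members = np.arange(10)
        oj, othr, oimp = split_oracle(G, resid, members, min_node=2)
        j, thr, imp = best_split(resid, members, G, min_node=2)
        assert (j, thr) == (oj, othr)
        assert imp == pytest.approx(oimp, rel=1e-10)

    def test_argmax_property_random_instances(self, rng):
        for _ in range(20):
            n, P = 40, 8
            G = rng.integers(0, 3, size=(n, P)).astype(float)
            resid = rng.normal(size=n)
            members = rng.choice(n, size=30, replace=False)
            oj, othr, oimp = split_oracle(G, resid, members, min_node=3)
            j, thr, imp = best_split(resid, members, G, min_node=3)
            assert imp == pytest.approx(oimp, rel=1e-10)
            assert (j, thr) == (oj, othr)

    def test_no_eligible_split_returns_sentinel(self, rng):
        G = rng.integers(0, 3, size=(12, 3)).astype(float)
        j, thr, imp = best_split(np.full(12, 2.5), np.arange(12), G,
                                 min_node=2)
        assert j == -1
        assert imp == 0.0


class TestFitTree:
    def test_stump_predicts_daughter_means(self, rng):
        n = 80
        G = rng.integers(0, 3, size=(n, 4)).astype(float)
        resid = 0.6 * (G[:, 2] >= 1) + rng.normal(0, 0.2, n)
        tree = fit_tree(resid, np.arange(n), G, k=1, min_node=5)
        assert tree["n_nodes"] == 3
        pred = tree["predict"](G)
        left = pred[G[:, tree["feature"][0]] < tree["threshold"][0]]
        assert np.allclose(left, left[0])
        split_var = tree["feature"][0]
        mask = G[:, split_var] < tree["threshold"][0]
        assert pred[mask][0] == pytest.approx(resid[mask].mean())
        assert pred[~mask][0] == pytest.approx(resid[~mask].mean())

    def test_tree_never_increases_bag_sse(self, rng):
        for s in range(5):
            r = np.random.default_rng(s)
            n = 150
            G = r.integers(0, 3, size=(n, 10)).astype(float)
            resid = r.normal(size=n)
            tree = fit_tree(resid, np.arange(n), G, k=5, min_node=10)
            pred = tree["predict"](G)
            assert np.sum((resid - pred) ** 2) <= np.sum(
                (resid - resid.mean()) ** 2) + 1e-9

    def test_constant_residuals_give_single_terminal_node(self, rng):
        G = rng.integers(0, 3, size=(50, 5)).astype(float)
        tree = fit_tree(np.full(50, 1.23), np.arange(50), G, k=5)
        assert tree["n_nodes"] == 1
        assert tree["predict"](G) == pytest.approx(1.23)

    def test_interaction_residuals_use_both_snps(self):
        # residuals depend on g1*g2: a depth-5 tree should recruit both
        used_both = 0
        for s in range(100):
            r = np.random.default_rng(1000 + s)
            n = 300
            G = r.binomial(2, 0.5, size=(n, 10)).astype(float)
            resid = ((G[:, 0] - 1) * (G[:, 1] - 1)
                     + r.normal(0, 0.5, n))
            tree = fit_tree(resid, np.arange(n), G, k=5, min_node=10)
            feats = set(tree["feature"][tree["feature"] >= 0])
            used_both += {0, 1} <= feats
        assert used_both >= 50


class TestBoosting:
    def test_single_tree_reduction(self, rng):
        n = 200
        G = rng.integers(0, 3, size=(n, 6)).astype(float)
        y = 1.0 * (G[:, 4] >= 1.5) + rng.normal(0, 0.3, n)
        model = BoostedTreeRegressor(n_trees=1, interaction_depth=1,
                                     shrinkage=1.0, bag_fraction=1.0,
                                     random_state=0).fit(G, y)
        # model == F0 + one stump; importance concentrated on one SNP
        assert (model.feature_importances_ > 0).sum() == 1
        tree = fit_tree(y - y.mean(), np.arange(n), G, k=1, min_node=10)
        assert np.allclose(model.predict(G),
                           y.mean() + tree["predict"](G))

    def test_training_sse_nonincreasing_in_trees(self, rng):
        n = 300
        G = rng.integers(0, 3, size=(n, 15)).astype(float)
        y = 0.5 * G[:, 3] + rng.normal(size=n)
        sses = []
        for M in (5, 20, 80):
            m = BoostedTreeRegressor(n_trees=M, interaction_depth=2,
                                     shrinkage=0.3, bag_fraction=1.0,
                                     random_state=0).fit(G, y)
            sses.append(np.sum((y - m.train_predictions_) ** 2))
        assert sses[0] >= sses[1] >= sses[2]

    def test_vim_conservation_identity(self, rng):
        n = 250
        G = rng.integers(0, 3, size=(n, 12)).astype(float)
        y = 0.4 * G[:, 1] - 0.5 * (G[:, 6] >= 1) + rng.normal(size=n)
        m = BoostedTreeRegressor(n_trees=60, interaction_depth=3,
                                 shrinkage=0.1, random_state=3).fit(G, y)
        total_vim = m.feature_importances_.sum()
        total_split = m.split_improvements()["improvement"].sum()
        assert abs(total_vim - total_split) <= 1e-8 * total_vim

    def test_column_permutation_permutes_vim(self, rng):
        n = 200
        G = rng.integers(0, 3, size=(n, 10)).astype(float)
        y = 0.6 * G[:, 2] + rng.normal(size=n)
        perm = rng.permutation(10)
        a = BoostedTreeRegressor(n_trees=40, interaction_depth=2,
                                 shrinkage=0.2, random_state=7).fit(G, y)
        b = BoostedTreeRegressor(n_trees=40, interaction_depth=2,
                                 shrinkage=0.2, random_state=7).fit(G[:, perm], y)
        # same seed => same bags; importances follow the columns
        assert np.allclose(b.feature_importances_,
                           a.feature_importances_[perm])

    def test_matches_sklearn_reference_exactly(self, rng):
        """Deterministic (bag=1) boosting agrees with sklearn's
        GradientBoostingRegressor under identical settings."""
        from sklearn.ensemble import GradientBoostingRegressor
        n, P = 300, 25
        G = rng.integers(0, 3, size=(n, P)).astype(float)
        y = 0.4 * G[:, 3] - 0.3 * (G[:, 7] >= 1) + rng.normal(0, 1, n)
        ours = BoostedTreeRegressor(n_trees=30, interaction_depth=3,
                                    shrinkage=0.1, bag_fraction=1.0,
                                    min_node=10, random_state=0).fit(G, y)
        sk = GradientBoostingRegressor(n_estimators=30, learning_rate=0.1,
                                       max_leaf_nodes=4, min_samples_leaf=10,
                                       subsample=1.0, random_state=0).fit(G, y)
        assert np.abs(ours.predict(G) - sk.predict(G)).max() < 1e-10

    def test_depth_one_blind_to_pure_interaction_depth_two_not(self):
        """Stumps cannot express a two-SNP interaction with zero main
        effects; two splits per tree can."""
        def interaction_data(seed, n=600, P=30, h2=0.25):
            r = np.random.default_rng(seed)
            G = r.binomial(2, 0.5, size=(n, P + 2)).astype(float)
            c1, c2 = G[:, P] - 1, G[:, P + 1] - 1
            y = np.sqrt(h2 / 0.25) * c1 * c2 + r.normal(0, np.sqrt(1 - h2), n)
            return G, y

        mean_pct = {}
        for k in (1, 2):
            pcts = []
            for s in range(10):
                G, y = interaction_data(s)
                m = BoostedTreeRegressor(n_trees=200, interaction_depth=k,
                                         shrinkage=0.1, bag_fraction=0.5,
                                         random_state=s).fit(G, y)
                rk = rankdata(-m.feature_importances_)
                pcts.append((rk[30] + rk[31]) / 2 / 32 * 100)
            mean_pct[k] = np.mean(pcts)
        assert mean_pct[2] < 8          # interacting pair at the top
        assert mean_pct[1] > 15         # stumps near chance
        assert mean_pct[2] < mean_pct[1] / 3

    def test_shrinkage_path_stability(self):
        r = np.random.default_rng(99)
        n = 400
        G = r.binomial(2, 0.5, size=(n, 20)).astype(float)
        y = 0.5 * G[:, 5] + r.normal(size=n)
        a = BoostedTreeRegressor(n_trees=100, interaction_depth=2,
                                 shrinkage=0.2, bag_fraction=1.0,
                                 random_state=1).fit(G, y)
        b = BoostedTreeRegressor(n_trees=400, interaction_depth=2,
                                 shrinkage=0.05, bag_fraction=1.0,
                                 random_state=1).fit(G, y)
        assert np.corrcoef(a.train_predictions_,
                           b.train_predictions_)[0, 1] > 0.95

    def test_identical_seed_identical_fit(self, rng):
        G = rng.integers(0, 3, size=(100, 8)).astype(float)
        y = rng.normal(size=100)
        a = BoostedTreeRegressor(n_trees=20, shrinkage=0.1,
                                 random_state=5).fit(G, y)
        b = BoostedTreeRegressor(n_trees=20, shrinkage=0.1,
                                 random_state=5).fit(G, y)
        assert np.array_equal(a.feature_importances_, b.feature_importances_)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BoostedTreeRegressor(shrinkage=0.0).fit(np.zeros((20, 2)),
                                                    np.zeros(20))


class TestRanking:
    def test_zero_vim_snps_share_worst_average_rank(self, rng):
        G = rng.integers(0, 3, size=(60, 20)).astype(float)
        y = 2.0 * G[:, 0] + 0.01 * rng.normal(size=60)
        table = gbm_rank(G, y, n_trees=3, interaction_depth=1, shrinkage=1.0,
                         bag_fraction=1.0, random_state=0)
        zeros = table[table["vim"] == 0.0]
        assert len(zeros) > 1
        assert zeros["rank"].nunique() == 1
        expected = (len(table) + len(table) - len(zeros) + 1) / 2
        assert zeros["rank"].iloc[0] == pytest.approx(expected)

    def test_rank_invariant_to_normalization(self, rng):
        G = rng.integers(0, 3, size=(100, 10)).astype(float)
        y = 0.5 * G[:, 4] + rng.normal(size=100)
        model, table = fit_gbm(G, y, n_trees=30, interaction_depth=2,
                               shrinkage=0.2, random_state=1)
        by_norm = rankdata(-model.normalized_importances_, method="average")
        by_raw = rankdata(-model.feature_importances_, method="average")
        assert np.array_equal(by_raw, by_norm)

    def test_rank_agrees_with_independent_sort_oracle(self, rng):
        G = rng.integers(0, 3, size=(120, 15)).astype(float)
        y = 0.8 * G[:, 9] + rng.normal(size=120)
        model, table = fit_gbm(G, y, n_trees=40, interaction_depth=2,
                               shrinkage=0.2, random_state=2)
        vim = model.feature_importances_
        # oracle: rank by stable argsort of -vim (no ties among positives)
        order = np.argsort(-vim, kind="stable")
        oracle_rank = np.empty(len(vim))
        oracle_rank[order] = np.arange(1, len(vim) + 1)
        j = 9
        assert table.set_index("snp_id").loc["snp10", "rank"] == oracle_rank[j]
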