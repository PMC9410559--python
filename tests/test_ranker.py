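import numpy as np
import pytest

from pirank.metrics import ndcg_at_k
from pirank.ranker import (SCENARIO_A_CONFIG, SCENARIO_P_CONFIG, LambdaMARTRanker,
                           RankerConfig, compute_lambdas, fit_tree, load_model,
                           predict, save_model, train)
from tests.conftest import make_separable_groups


class TestComputeLambdas:
    def test_uniform_labels_give_zero_gradients(self):
        lam, hess = compute_lambdas(np.array([0.3, 0.1, 0.7]),
                                    np.array([1, 1, 1]), k=2)
        assert not lam.any() and not hess.any()
        lam, hess = compute_lambdas(np.array([0.3, 0.1]), np.array([0, 0]), k=2)
        assert not lam.any() and not hess.any()

    def test_two_candidate_equal_score_hand_value(self):
        # |dNDCG@2| = 1 - 1/log2(3); rho = 0.5 at equal scores.
        lam, hess = compute_lambdas(np.zeros(2), np.array([1, 0]), k=2, sigma=1.0)
        expected = 0.5 * (1 - 1 / np.log2(3))
        assert lam[0] == pytest.approx(expected, abs=1e-5)
        assert lam[1] == pytest.approx(-expected, abs=1e-5)
        assert lam[0] == pytest.approx(0.18454, abs=1e-5)
        assert (hess >= 0).all()

    def test_saturated_pair_has_vanishing_gradient(self):
        lam, _ = compute_lambdas(np.array([10.0, 0.0]), np.array([1, 0]), k=2)
        assert abs(lam[0]) < 1e-4

    @pytest.mark.parametrize("seed", range(10))
    def test_lambda_conservation_and_hessian_sign(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 25)
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        lam, hess = compute_lambdas(scores, labels, k=int(rng.integers(1, 10)))
        assert lam.sum() == pytest.approx(0.0, abs=1e-12)
        assert (hess >= 0).all()


class TestFitTree:
    def test_constant_targets_yield_single_leaf_newton_value(self):
        X = np.random.default_rng(0).uniform(size=(10, 4))
        targets = np.full(10, 2.0)
        weights = np.full(10, 1.0)
        tree = fit_tree(X, targets, weights, n_leaves=8)
        assert set(tree) == {"value"}
        assert tree["value"] == pytest.approx(20.0 / (10.0 + 1e-9))

    def test_perfect_split_on_feature_zero(self):
        X = np.array([[0.1, 9], [0.2, 1], [0.8, 5], [0.9, 2]])
        targets = np.array([-1.0, -1.0, 1.0, 1.0])
        tree = fit_tree(X, targets, np.ones(4), n_leaves=2)
        assert tree["feature"] == 0
        assert 0.2 < tree["threshold"] < 0.8
        assert tree["left"]["value"] < 0 < tree["right"]["value"]

    def test_leaf_cap_respected(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(200, 4))
        tree = fit_tree(X, rng.normal(size=200), np.ones(200), n_leaves=2)

        def count_leaves(node):
            if "value" in node:
                return 1
            return count_leaves(node["left"]) + count_leaves(node["right"])

        assert count_leaves(tree) <= 2


def _mean_train_ndcg(model, groups, k=5):
    values = []
    for _, X, y in groups:
        scores = model.predict(X)
        order = np.argsort(-scores, kind="stable")
        values.append(ndcg_at_k(np.asarray(y)[order], k))
    return float(np.mean(values))


class TestTraining:
    def test_zero_trees_predicts_constant(self, separable_groups):
        config = RankerConfig(n_trees=0, truncation_k=5, shrinkage=0.2, n_leaves=3)
        model = train(separable_groups, config)
        scores = model.predict(separable_groups[0][1])
        assert len(set(scores.tolist())) == 1
        assert model.feature_usage().tolist() == [0, 0, 0, 0]

    def test_separable_groups_reach_perfect_ndcg_within_20_trees(
            self, separable_groups):
        config = RankerConfig(n_trees=20, truncation_k=5, shrinkage=0.2,
                              n_leaves=3)
        model = train(separable_groups, config)
        assert _mean_train_ndcg(model, separable_groups, k=5) == pytest.approx(1.0)
        # and every positive outranks every negative
        for _, X, y in separable_groups:
            scores = model.predict(X)
            assert scores[y == 1].min() > scores[y == 0].max()

    def test_training_never_degrades_mean_ndcg(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            groups = make_separable_groups(rng, n_groups=4, n_candidates=8)
            # add label noise so the task is not trivially separable
            for _, X, y in groups:
                X += rng.normal(scale=0.3, size=X.shape)
            config = RankerConfig(n_trees=10, truncation_k=4, shrinkage=0.3,
                                  n_leaves=3)
            zero = train(groups, RankerConfig(n_trees=0, truncation_k=4,
                                              shrinkage=0.3, n_leaves=3))
            fitted = train(groups, config)
            assert _mean_train_ndcg(fitted, groups, k=4) >= \
                _mean_train_ndcg(zero, groups, k=4)

    def test_untrainable_groups_are_an_error(self):
        groups = [("q0", np.zeros((3, 4)), np.array([1, 1, 1]))]
        with pytest.raises(ValueError):
            train(groups, RankerConfig(n_trees=5))

    def test_no_positive_groups_are_skipped_but_rankable(self, separable_groups):
        groups = separable_groups + [
            ("empty", np.random.default_rng(0).uniform(size=(5, 4)),
             np.zeros(5, dtype=int))]
        config = RankerConfig(n_trees=5, truncation_k=5, shrinkage=0.2,
                              n_leaves=3)
        model = train(groups, config)
        ranked = model.rank_group("empty", list("abcde"), groups[-1][1])
        assert sorted(e[2] for e in ranked.entries) == [1, 2, 3, 4, 5]


class TestPrediction:
    def test_zero_tree_ranking_keeps_input_order(self, separable_groups):
        model = train(separable_groups, RankerConfig(n_trees=0))
        _, X, _ = separable_groups[0]
        ranked = model.rank_group("q", [f"d{i}" for i in range(len(X))], X)
        assert [e[0] for e in ranked.entries] == [f"d{i}" for i in range(len(X))]

    def test_scores_non_increasing_with_rank(self, separable_groups):
        model = train(separable_groups,
                      RankerConfig(n_trees=10, shrinkage=0.2, n_leaves=3))
        for q, X, _ in separable_groups:
            ranked = model.rank_group(q, [str(i) for i in range(len(X))], X)
            scores = [e[1] for e in ranked.entries]
            assert scores == sorted(scores, reverse=True)

    def test_predict_before_fit_is_an_error(self):
        with pytest.raises(ValueError):
            LambdaMARTRanker().predict(np.zeros((2, 4)))


class TestFeatureUsage:
    def test_counts_sum_to_internal_nodes(self, separable_groups):
        model = train(separable_groups,
                      RankerConfig(n_trees=15, shrinkage=0.2, n_leaves=4))
        usage = model.feature_usage()

        def internal(node):
            if "value" in node:
                return 0
            return 1 + internal(node["left"]) + internal(node["right"])

        assert usage.sum() == sum(internal(t) for t in model.trees_)
        assert usage.sum() > 0


class TestPersistence:
    def test_seeded_training_is_bit_reproducible(self, tmp_path,
                                                 separable_groups):
        config = RankerConfig(n_trees=12, truncation_k=5, shrinkage=0.2,
                              n_leaves=3, seed=9)
        p1, p2 = tmp_path / "m1.txt", tmp_path / "m2.txt"
        save_model(train(separable_groups, config), p1)
        save_model(train(separable_groups, config), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_save_load_round_trip(self, tmp_path, separable_groups):
        model = train(separable_groups,
                      RankerConfig(n_trees=7, shrinkage=0.15, n_leaves=5))
        path = tmp_path / "model.txt"
        save_model(model, path)
        back = load_model(path)
        assert back.get_params() == model.get_params()
        X = separable_groups[0][1]
        assert np.array_equal(back.predict(X), model.predict(X))

    def test_load_rejects_foreign_files(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text("not a model\n")
        with pytest.raises(ValueError):
            load_model(path)


def test_scenario_defaults_match_tuned_optima():
    assert (SCENARIO_A_CONFIG.n_trees, SCENARIO_A_CONFIG.truncation_k,
            SCENARIO_A_CONFIG.shrinkage, SCENARIO_A_CONFIG.n_leaves) == \
        (120, 14, 0.22, 3)
    assert (SCENARIO_P_CONFIG.n_trees, SCENARIO_P_CONFIG.truncation_k,
            SCENARIO_P_CONFIG.shrinkage, SCENARIO_P_CONFIG.n_leaves) == \
        (30, 15, 0.10, 29)


def test_config_validation():
    with pytest.raises(ValueError):
        RankerConfig(shrinkage=0.0)
    with pytest.raises(ValueError):
        RankerConfig(n_leaves=1)


def test_ranking_agrees_with_established_lambdarank():
    """Cross-check: pairwise-order agreement with LightGBM's lambdarank on a
    noisy fixture exceeds 90%."""
    lgb = pytest.importorskip("lightgbm")
    rng = np.random.default_rng(3)
    groups = make_separable_groups(rng, n_groups=15, n_candidates=15, n_pos=4)
    for _, X, _ in groups:
        X += rng.normal(scale=0.25, size=X.shape)
    config = RankerConfig(n_trees=30, truncation_k=10, shrinkage=0.1, n_leaves=4)
    ours = train(groups, config)
    X_all = np.vstack([g[1] for g in groups])
    y_all = np.concatenate([g[2] for g in groups])
    sizes = [len(g[2]) for g in groups]
    ref = lgb.LGBMRanker(n_estimators=30, learning_rate=0.1, num_leaves=4,
                         min_child_samples=1, random_state=0, verbose=-1)
    ref.fit(X_all, y_all, group=sizes)
    agree = total = 0
    offset = 0
    for _, X, y in groups:
        a = ours.predict(X)
        b = ref.predict(X_all[offset:offset + len(y)])
        offset += len(y)
        for i in range(len(y)):
            for j in range(i + 1, len(y)):
                if a[i] == a[j] or b[i] == b[j]:
                    continue
                total += 1
                agree += (a[i] > a[j]) == (b[i] > b[j])
    assert total > 0
    assert agree / total >= 0.9
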