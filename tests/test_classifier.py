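import json
import math

import numpy as np
import pytest

from plantmir import (
    ATTRIBUTE_NAMES,
    AttributeVector,
    CostMatrix,
    EmptyDatasetError,
    MISSING,
    SchemaError,
    TreeParams,
    attribute_usage,
    boost,
    induce_tree,
    load_model,
    predict,
    predict_matrix,
    save_model,
    winnow_importance,
)
from plantmir.classifier import BoostedModel, TreeNode, apply_tree
from tests.oracles import gain_ratio_oracle

A = len(ATTRIBUTE_NAMES)
CAUSAL = 6  # DuplexEnergy column used as the planted causal attribute


def planted_rule_data(n=100, noise=0.0, seed=0):
    """y = 1 iff X[:, CAUSAL] > 0.5; other columns are pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, A))
    y = (X[:, CAUSAL] > 0.5).astype(np.int8)
    if noise:
        flip = rng.uniform(size=n) < noise
        y[flip] = 1 - y[flip]
    return X, y


def _vector_from_row(row):
    return {name: float(v) for name, v in zip(ATTRIBUTE_NAMES, row)}


class TestInduceTree:
    def test_noiseless_single_threshold_rule_recovered(self):
        X, y = planted_rule_data(100, seed=1)
        tree = induce_tree(X, y)
        assert tree.attribute == ATTRIBUTE_NAMES[CAUSAL]
        lo = X[y == 0, CAUSAL].max()
        hi = X[y == 1, CAUSAL].min()
        assert lo < tree.threshold < hi
        assert tree.left.is_leaf and tree.right.is_leaf
        assert (apply_tree(tree, X) == y).all()

    def test_constant_attributes_give_majority_leaf(self):
        X = np.ones((30, A))
        y = np.array([1] * 10 + [0] * 20, dtype=np.int8)
        tree = induce_tree(X, y)
        assert tree.is_leaf and tree.klass == 0

    def test_xor_needs_two_levels_and_fits_training_data(self):
        # Near-balanced XOR over two informative attributes.  (At exact
        # 25/25/25/25 balance both marginal splits have information gain
        # exactly 0 and no admissible split exists, so one archetype gets
        # an extra case to give the root a strictly positive gain.)
        counts = (25, 25, 25, 26)
        X = np.zeros((sum(counts), A))
        a, b = 2, 5
        X[:, a] = np.repeat([0.0, 0.0, 1.0, 1.0], counts)
        X[:, b] = np.repeat([0.0, 1.0, 0.0, 1.0], counts)
        y = (X[:, a] != X[:, b]).astype(np.int8)
        tree = induce_tree(X, y, params=TreeParams(prune=False))
        assert (apply_tree(tree, X) == y).all()
        internal = 0
        stack = [tree]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                internal += 1
                stack.extend([nd.left, nd.right])
        assert internal >= 2

    def test_chosen_split_maximizes_gain_ratio_exhaustively(self):
        rng = np.random.default_rng(7)
        for trial in range(6):
            X = rng.uniform(size=(24, A))
            y = rng.integers(0, 2, size=24).astype(np.int8)
            tree = induce_tree(X, y, params=TreeParams(prune=False, max_depth=1))
            best = -1.0
            for j in range(A):
                for _thr, ratio, _gain in gain_ratio_oracle(X[:, j], y):
                    best = max(best, ratio)
            if tree.is_leaf:
                assert best < 0  # no admissible split anywhere
            else:
                j = list(ATTRIBUTE_NAMES).index(tree.attribute)
                chosen = [
                    r for thr, r, _g in gain_ratio_oracle(X[:, j], y)
                    if thr == pytest.approx(tree.threshold)
                ]
                assert chosen and chosen[0] == pytest.approx(best)

    def test_pruned_estimate_never_worse_than_unpruned(self):
        from plantmir.classifier import _subtree_pessimistic

        X, y = planted_rule_data(200, noise=0.2, seed=11)
        raw = induce_tree(X, y, params=TreeParams(prune=False))
        pruned = induce_tree(X, y, params=TreeParams(prune=True))
        assert _subtree_pessimistic(pruned, 0.25) <= _subtree_pessimistic(raw, 0.25) + 1e-9

    def test_missing_values_follow_the_heavier_branch(self):
        X, y = planted_rule_data(60, seed=13)
        tree = induce_tree(X, y)
        row = np.full((1, A), np.nan)
        expected = tree.left if tree.missing_route == "left" else tree.right
        assert apply_tree(tree, row)[0] == expected.klass

    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyDatasetError):
            induce_tree(np.empty((0, A)), np.empty(0, dtype=np.int8))


class TestBoost:
    def test_separable_data_stops_after_one_trial(self):
        X, y = planted_rule_data(100, seed=17)
        model = boost(X, y, trials=10)
        assert model.trials_run == 1
        assert model.epsilons == [0.0]

    def test_single_trial_equals_plain_tree(self):
        X, y = planted_rule_data(150, noise=0.15, seed=19)
        model = boost(X, y, trials=1)
        labels, _ = predict_matrix(model, X)
        assert (labels == apply_tree(induce_tree(X, y), X)).all()

    def test_ensemble_satisfies_adaboost_training_bound(self):
        X, y = planted_rule_data(400, noise=0.25, seed=23)
        model = boost(X, y, trials=10, params=TreeParams(max_depth=3))
        assert model.trials_run > 1
        labels, _ = predict_matrix(model, X)
        # weighted-majority training error vs prod of 2 sqrt(eps(1-eps))
        err = float((labels != y).mean())
        bound = math.prod(2 * math.sqrt(e * (1 - e)) for e in model.epsilons)
        assert err <= bound + 1e-9

    def test_boosting_does_not_hurt_training_error(self):
        X, y = planted_rule_data(400, noise=0.25, seed=29)
        single = boost(X, y, trials=1, params=TreeParams(max_depth=3))
        ens = boost(X, y, trials=10, params=TreeParams(max_depth=3))
        e1 = float((predict_matrix(single, X)[0] != y).mean())
        e10 = float((predict_matrix(ens, X)[0] != y).mean())
        assert e10 <= e1 + 1e-9


def _stub_model(weights_mi_not):
    """An ensemble of constant-leaf trees with given (miRNA, not) weights."""
    trees = []
    for klass, weight in weights_mi_not:
        trees.append((TreeNode(klass=klass, class_weights=(1, 1),
                               training_count=2, error_count=0), weight))
    return BoostedModel(trees=trees, epsilons=[0.1] * len(trees),
                        trials_requested=len(trees), cost=CostMatrix(),
                        params=TreeParams())


class TestPredict:
    def test_confidence_is_vote_share(self):
        model = _stub_model([(1, 0.6), (0, 0.4)])
        p = predict(model, _vector_from_row(np.zeros(A)))
        assert p.label == "miRNA"
        assert p.confidence == pytest.approx(0.6)

    def test_exact_tie_goes_to_not_mirna(self):
        model = _stub_model([(1, 0.5), (0, 0.5)])
        p = predict(model, _vector_from_row(np.zeros(A)))
        assert p.label == "not_miRNA"

    def test_cost_rule_matches_expected_cost_enumeration(self):
        for p_mi in np.linspace(0, 1, 11):
            for fp_cost in (0.5, 1.0, 5.0):
                for fn_cost in (0.5, 1.0, 2.0):
                    model = _stub_model([(1, p_mi), (0, 1 - p_mi)]) if 0 < p_mi < 1 \
                        else _stub_model([(1 if p_mi else 0, 1.0)])
                    model.cost = CostMatrix(fp_cost=fp_cost, fn_cost=fn_cost)
                    got = predict(model, _vector_from_row(np.zeros(A))).label
                    exp_mi = (1 - p_mi) * fp_cost
                    exp_not = p_mi * fn_cost
                    want = "miRNA" if exp_mi < exp_not else "not_miRNA"
                    assert got == want, (p_mi, fp_cost, fn_cost)

    def test_schema_mismatch_raises(self):
        X, y = planted_rule_data(50, seed=31)
        model = boost(X, y, trials=1)
        with pytest.raises(SchemaError):
            predict(model, {"bogus": 1.0})

    def test_missing_values_are_accepted_at_prediction_time(self):
        X, y = planted_rule_data(80, seed=37)
        model = boost(X, y, trials=3)
        values = _vector_from_row(X[0])
        values[ATTRIBUTE_NAMES[CAUSAL]] = MISSING
        assert predict(model, values).label in ("miRNA", "not_miRNA")


class TestReporting:
    def test_usage_of_single_split_tree(self):
        X, y = planted_rule_data(100, seed=41)
        model = boost(X, y, trials=1)
        usage = attribute_usage(model, X)
        assert usage[ATTRIBUTE_NAMES[CAUSAL]] == 100.0
        assert all(v == 0.0 for k, v in usage.items() if k != ATTRIBUTE_NAMES[CAUSAL])
        assert set(usage) == set(ATTRIBUTE_NAMES)

    def test_winnowing_ranks_planted_attribute_first(self):
        X, y = planted_rule_data(600, noise=0.05, seed=43)
        imp = winnow_importance(X, y, trials=3)
        assert set(imp) == set(ATTRIBUTE_NAMES)
        top = max(imp, key=imp.get)
        assert top == ATTRIBUTE_NAMES[CAUSAL]
        others = [v for k, v in imp.items() if k != top]
        assert max(abs(v) for v in others) < 2.0  # noise attributes near zero


class TestSerialization:
    def test_round_trip_predicts_identically(self, tmp_path):
        X, y = planted_rule_data(300, noise=0.2, seed=47)
        model = boost(X, y, trials=5)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        rng = np.random.default_rng(49)
        Xnew = rng.uniform(size=(500, A))
        Xnew[rng.uniform(size=Xnew.shape) < 0.05] = np.nan
        a, _ = predict_matrix(model, Xnew)
        b, _ = predict_matrix(back, Xnew)
        assert (a == b).all()

    def test_identical_training_gives_byte_identical_model_files(self, tmp_path):
        X, y = planted_rule_data(200, noise=0.1, seed=53)
        paths = []
        for name in ("a.json", "b.json"):
            model = boost(X, y, trials=5, seed=5)
            save_model(model, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert json.loads(paths[0].read_text())["config_hash"]
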