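"""Regression tree: split oracle, surrogates, pruning, importance."""

import numpy as np
import pandas as pd
import pytest

from twinpillars.cart import (
    best_split,
    cv_prune,
    find_surrogates,
    fit_regression_tree,
    grow_tree,
    variable_importance,
)
from twinpillars.synth import generate_cart_benchmark


def brute_force_best_split(y, X, minbucket=1):
    """Exhaustive SSE minimization over all binary splits (oracle)."""
    def sse(a):
        return float(((a - a.mean()) ** 2).sum()) if a.size else 0.0

    best = None
    for j in range(X.shape[1]):
        x = X[:, j]
        ok = ~np.isnan(x)
        if not ok.any():
            continue
        yv, xv = y[ok], x[ok]
        left = xv == 1.0
        if left.sum() < minbucket or (~left).sum() < minbucket:
            continue
        imp = sse(yv) - sse(yv[left]) - sse(yv[~left])
        if imp > 0 and (best is None or imp > best[1] + 1e-12):
            best = (j, imp)
    return best


class TestBestSplit:
    def test_matches_exhaustive_oracle(self):
        """Every primary split equals brute-force SSE minimization on
        random fixtures with <= 6 binary predictors and <= 50 cases."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(5, 51))
            p = int(rng.integers(2, 7))
            X = rng.choice([0.0, 1.0, np.nan], size=(n, p), p=[0.45, 0.45, 0.1])
            y = rng.normal(size=n)
            variables = [f"v{j}" for j in range(p)]
            got = best_split(y, X, variables, minbucket=1)
            want = brute_force_best_split(y, X, minbucket=1)
            if want is None:
                assert got is None
            else:
                assert variables.index(got[0]) == want[0]
                assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_constant_outcome_no_split(self):
        X = np.array([[1.0, 0.0]] * 10 + [[0.0, 1.0]] * 10)
        y = np.full(20, 3.7)
        assert best_split(y, X, ["a", "b"]) is None

    def test_perfect_split_zero_child_sse(self):
        rng = np.random.default_rng(1)
        x = rng.choice([0.0, 1.0], 40)
        X = np.column_stack([rng.choice([0.0, 1.0], 40), x])
        y = x.copy()
        var, imp = best_split(y, X, ["noise", "signal"])
        assert var == "signal"
        assert imp == pytest.approx(float(((y - y.mean()) ** 2).sum()))

    def test_tie_breaks_by_canonical_order(self):
        x = np.array([1.0, 1.0, 0.0, 0.0])
        X = np.column_stack([x, x])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        var, _ = best_split(y, X, ["first", "second"])
        assert var == "first"


class TestSurrogates:
    def test_identical_variable_is_perfect_first_surrogate(self):
        rng = np.random.default_rng(2)
        x = rng.choice([0.0, 1.0], 60)
        X = np.column_stack([x, x, rng.choice([0.0, 1.0], 60)])
        surr = find_surrogates(x == 1.0, X, ["prim", "twin", "other"], "prim")
        assert surr[0].variable == "twin"
        assert surr[0].agreement == 1.0
        assert surr[0].adjusted == 1.0

    def test_independent_variable_excluded_by_majority_baseline(self):
        rng = np.random.default_rng(3)
        x = rng.choice([0.0, 1.0], 2000, p=[0.3, 0.7])
        indep = rng.choice([0.0, 1.0], 2000)
        X = np.column_stack([x, indep])
        surr = find_surrogates(x == 1.0, X, ["prim", "indep"], "prim")
        assert all(s.variable != "indep" for s in surr)

    def test_hand_enumerated_fixture(self):
        """12-case fixture: agreement computed by hand.

        primary routing (go left) : 1 1 1 1 1 1 0 0 0 0 0 0
        candidate                 : 1 1 1 1 1 0 0 0 0 0 1 1
        orientation 1->left agrees on 5 + 4 = 9/12; majority baseline 6/12.
        """
        primary_left = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]) == 1
        cand = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1], float)
        X = cand[:, None]
        surr = find_surrogates(primary_left, X, ["cand"], primary_var="prim")
        assert len(surr) == 1
        assert surr[0].agreement == pytest.approx(9 / 12)
        assert surr[0].left_value == 1.0
        assert surr[0].adjusted == pytest.approx((9 / 12 - 0.5) / 0.5)


class TestGrowTree:
    def test_minsplit_root_leaf(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"a_met": rng.choice([0.0, 1.0], 19), "y": rng.normal(size=19)}
        )
        tree = grow_tree(df, "y", ["a_met"], minsplit=20)
        assert tree.root.is_leaf
        assert tree.root.n == 19

    def test_benchmark_topology_and_leaf_means(self):
        df = generate_cart_benchmark(4000, seed=2)
        tree = fit_regression_tree(df, "bmi", seed=0)
        assert tree.root.split_var == "sedentary_met"
        right = tree.nodes[tree.root.right]  # sedentary not met
        assert right.split_var == "mvpa_met"
        left = tree.nodes[tree.root.left]
        assert left.node_mean == pytest.approx(25.0, abs=0.3)
        assert tree.nodes[right.left].node_mean == pytest.approx(26.0, abs=0.3)
        assert tree.nodes[right.right].node_mean == pytest.approx(27.0, abs=0.3)
        imp = variable_importance(tree)
        assert imp.index[0] == "sedentary_met"
        assert imp["sedentary_met"] > imp["mvpa_met"] > 0

    def test_no_missingness_routing_equals_primary_only(self):
        df = generate_cart_benchmark(1500, seed=3, missing_rate=0.0)
        tree = grow_tree(df, "bmi")
        pred_with = tree.predict(df)
        for nd in tree.nodes.values():
            nd.surrogates = []
        pred_without = tree.predict(df)
        assert np.array_equal(pred_with, pred_without)

    def test_row_permutation_invariance(self):
        df = generate_cart_benchmark(800, seed=6)
        tree_a = grow_tree(df, "bmi")
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        tree_b = grow_tree(shuffled, "bmi")
        assert tree_a.root.split_var == tree_b.root.split_var
        assert tree_a.root.improvement == pytest.approx(tree_b.root.improvement)
        imp_a = variable_importance(tree_a)
        imp_b = variable_importance(tree_b)
        assert np.allclose(imp_a.sort_index(), imp_b.sort_index())

    def test_node_accounting_identities(self):
        df = generate_cart_benchmark(1200, seed=7)
        tree = grow_tree(df, "bmi")
        for nd in tree.nodes.values():
            if nd.is_leaf:
                continue
            left, right = tree.nodes[nd.left], tree.nodes[nd.right]
            assert left.n + right.n == nd.n
            assert nd.fraction_of_root == pytest.approx(
                left.fraction_of_root + right.fraction_of_root
            )
            weighted = (left.n * left.node_mean + right.n * right.node_mean) / nd.n
            assert nd.node_mean == pytest.approx(weighted, abs=1e-9)
            assert nd.improvement >= 0


class TestPruning:
    def test_pure_noise_prunes_to_root(self):
        """Under the one-SE selection rule a pure-noise outcome collapses
        to the root leaf in nearly every seeded replicate."""
        hits = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(2000 + rep)
            n = 300
            df = pd.DataFrame({f"v{j}_met": rng.choice([0.0, 1.0], n)
                               for j in range(5)})
            df["y"] = rng.normal(size=n)
            tree = fit_regression_tree(
                df, "y", [f"v{j}_met" for j in range(5)], seed=rep,
                prune_rule="1se",
            )
            hits += tree.n_splits() == 0
        assert hits >= 0.95 * reps

    def test_cp_sequence_monotone(self):
        df = generate_cart_benchmark(2000, seed=8)
        tree = grow_tree(df, "bmi", cp=0.001)
        _, table = cv_prune(tree, df, folds=5, seed=0)
        t = table.sort_values("alpha")
        assert (np.diff(t["nsplit"]) <= 0).all()
        assert (np.diff(t["rel_error"]) >= -1e-12).all()

    def test_pruning_preserves_sse_accounting(self):
        df = generate_cart_benchmark(2000, seed=9)
        tree = grow_tree(df, "bmi", cp=0.001)
        pruned, _ = cv_prune(tree, df, folds=5, seed=1)
        for nid, nd in pruned.nodes.items():
            full = tree.nodes[nid]
            assert nd.n == full.n
            assert nd.sse == pytest.approx(full.sse)

    def test_too_few_cases_for_folds(self):
        df = generate_cart_benchmark(100, seed=10)
        tree = grow_tree(df, "bmi")
        with pytest.raises(ValueError):
            cv_prune(tree, df.iloc[:5], folds=10)

    def test_fold_assignment_seeded(self):
        df = generate_cart_benchmark(1000, seed=11)
        tree = grow_tree(df, "bmi")
        _, t1 = cv_prune(tree, df, folds=5, seed=3)
        _, t2 = cv_prune(tree, df, folds=5, seed=3)
        pd.testing.assert_frame_equal(t1, t2)


class TestImportance:
    def test_single_split_all_credit(self):
        rng = np.random.default_rng(12)
        x = rng.choice([0.0, 1.0], 200)
        df = pd.DataFrame(
            {"sig_met": x, "noise_met": rng.choice([0.0, 1.0], 200),
             "y": x + rng.normal(0, 0.1, 200)}
        )
        tree = grow_tree(df, "y", ["sig_met", "noise_met"])
        imp = variable_importance(tree)
        assert imp["sig_met"] > 95
        assert imp.sum() == pytest.approx(100.0, abs=0.5)

    def test_sums_to_100_on_random_fixtures(self):
        for seed in range(5):
            df = generate_cart_benchmark(600, seed=seed)
            tree = fit_regression_tree(df, "bmi", seed=seed)
            if tree.n_splits() == 0:
                continue
            assert variable_importance(tree).sum() == pytest.approx(100, abs=0.5)

    def test_never_used_variable_scores_zero(self):
        rng = np.random.default_rng(13)
        x = rng.choice([0.0, 1.0], 300)
        # c is constant: it can never split nor beat the majority baseline
        df = pd.DataFrame({"a_met": x, "b_met": 1.0 - x,
                           "c_met": np.zeros(300),
                           "y": 2 * x + rng.normal(0, 0.1, 300)})
        tree = grow_tree(df, "y", ["a_met", "b_met", "c_met"])
        imp = variable_importance(tree)
        # b is a perfect (anti-aligned) surrogate; c is noise
        assert imp["b_met"] > 0
        assert imp["c_met"] == pytest.approx(0.0, abs=1e-9)


class TestSklearnCrossCheck:
    def test_first_split_matches_sklearn(self):
        """On complete data the root split (variable and SSE improvement)
        agrees with scikit-learn's regression tree."""
        sklearn = pytest.importorskip("sklearn.tree")
        df = generate_cart_benchmark(2500, seed=14, missing_rate=0.0)
        variables = [c for c in df.columns if c.endswith("_met")]
        X = df[variables].to_numpy()
        y = df["bmi"].to_numpy()
        sk = sklearn.DecisionTreeRegressor(max_depth=1).fit(X, y)
        tree = grow_tree(df, "bmi", variables, minbucket=1)
        assert tree.root.split_var == variables[sk.tree_.feature[0]]
        n = sk.tree_.n_node_samples
        sk_improvement = (
            n[0] * sk.tree_.impurity[0]
            - n[1] * sk.tree_.impurity[1]
            - n[2] * sk.tree_.impurity[2]
        )
        assert tree.root.improvement == pytest.approx(sk_improvement, rel=1e-9)
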