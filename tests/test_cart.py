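import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from parityniche import (
    best_split,
    classification_summary,
    cost_complexity_sequence,
    cross_validate,
    grow_tree,
    predict,
    prune_1se,
    prune_at,
    variable_importance,
)
from parityniche.cart import CvProfile, _branch_risk

from conftest import random_classification_data


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def gini(y):
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return 1.0 - np.sum(p**2)


def brute_force_best_split(X, y, minbucket=1):
    """Exhaustive scan over every variable x threshold midpoint."""
    n = len(y)
    best = None
    for j in range(X.shape[1]):
        xs = np.unique(X[:, j])
        for lo, hi in zip(xs, xs[1:]):
            thr = (lo + hi) / 2.0
            left = X[:, j] < thr
            n_l = left.sum()
            if n_l < minbucket or n - n_l < minbucket:
                continue
            dec = gini(y) - n_l / n * gini(y[left]) - (n - n_l) / n * gini(y[~left])
            if best is None or dec > best[0] + 1e-12:
                best = (dec, j, thr)
    return best


def enumerate_subtrees(node):
    """All pruned subtrees as (misclassification count, n_leaves) pairs."""
    leaf = (node.risk, 1)
    if node.is_leaf:
        return [leaf]
    out = [leaf]
    for rl, ll in enumerate_subtrees(node.left):
        for rr, lr in enumerate_subtrees(node.right):
            out.append((rl + rr, ll + lr))
    return out


# ---------------------------------------------------------------------------
# split search
# ---------------------------------------------------------------------------


class TestBestSplit:
    def test_pure_node_returns_none(self):
        X = np.arange(10.0).reshape(-1, 1)
        assert best_split(X, np.zeros(10, dtype=int), ["x"]) is None

    def test_perfect_separation_yields_pure_children(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        s = best_split(X, y, ["x"])
        assert s.threshold == pytest.approx(6.5)
        assert s.decrease == pytest.approx(gini(y))  # children are pure

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 200)
        X = np.round(rng.normal(size=(n, 7)), 2)  # rounding forces ties
        y = (rng.random(n) < 0.4).astype(int)
        y[X[:, seed % 7] > 0.3] = 1  # signal on a rotating variable
        expect = brute_force_best_split(X, y)
        got = best_split(X, y, [f"v{j}" for j in range(7)])
        if expect is None:
            assert got is None
        else:
            dec, j, thr = expect
            assert got.var_index == j
            assert got.threshold == pytest.approx(thr)
            assert got.decrease == pytest.approx(dec, rel=1e-10)

    def test_minbucket_restricts_candidates(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1, 0, 0, 0])
        # unrestricted best split isolates the first point ...
        assert best_split(X, y, ["x"]).threshold == pytest.approx(1.5)
        # ... which a 2-case minimum bucket forbids
        s = best_split(X, y, ["x"], minbucket=2)
        assert s is None or s.threshold == pytest.approx(2.5)


class TestGrowTree:
    def test_single_class_gives_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.warns(UserWarning, match="one class"):
            tree = grow_tree(X, np.zeros(30, dtype=int), ["a", "b"])
        assert tree.root.is_leaf
        assert tree.n_leaves() == 1

    def test_separable_data_reaches_perfect_training_accuracy(self):
        X, y = random_classification_data(3, n=80, shift=6.0)
        tree = grow_tree(X, y, ["a", "b", "c"], minsplit=4, minbucket=1)
        assert (predict(tree, X) == y).all()

    def test_child_counts_conserved_everywhere(self):
        X, y = random_classification_data(4, n=120, shift=1.0)
        tree = grow_tree(X, y, ["a", "b", "c"], minsplit=10, minbucket=3)
        for node in tree.internal_nodes():
            np.testing.assert_array_equal(
                node.counts, node.left.counts + node.right.counts
            )

    def test_duplicated_covariate_is_a_perfect_surrogate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        X = np.column_stack([x, x])
        y = (x > 0).astype(int)
        tree = grow_tree(X, y, ["v", "v_copy"], minsplit=10, minbucket=3)
        root = tree.root
        assert len(root.surrogates) == 1
        assert root.surrogates[0].agreement == 1.0
        imp = variable_importance(tree)
        # both columns share the credit equally
        assert imp["importance_pct"].to_numpy() == pytest.approx([50.0, 50.0])

    def test_missing_values_routed_through_surrogates(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        x2 = x + rng.normal(0, 0.05, 200)  # near-perfect surrogate
        y = (x > 0).astype(int)
        X = np.column_stack([x, x2])
        tree = grow_tree(X, y, ["v", "w"], minsplit=20, minbucket=7)
        X_miss = X.copy()
        X_miss[:50, 0] = np.nan
        pred = predict(tree, X_miss)
        assert (pred[:50] == y[:50]).mean() > 0.9


class TestCostComplexity:
    def test_single_split_tree_sequence(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        tree = grow_tree(X, y, ["x"], minsplit=2, minbucket=1)
        seq = cost_complexity_sequence(tree)
        assert [s for _, s in seq] == [2, 1]

    def test_infinite_cp_prunes_to_root(self):
        X, y = random_classification_data(7, n=100, shift=2.0)
        tree = grow_tree(X, y, ["a", "b", "c"], minsplit=8, minbucket=2)
        assert prune_at(tree, np.inf).root.is_leaf

    def test_sequence_matches_exhaustive_subtree_enumeration(self):
        """At every recorded cp the pruned tree minimizes R(T) + alpha*|leaves|
        over ALL pruned subtrees (alpha on the absolute risk scale)."""
        X, y = random_classification_data(8, n=100, p=4, shift=1.2)
        tree = grow_tree(X, y, list("abcd"), minsplit=15, minbucket=5)
        assert tree.n_leaves() >= 3
        all_subtrees = enumerate_subtrees(tree.root)
        root_risk = tree.root.risk
        seq = cost_complexity_sequence(tree)
        cps = [cp for cp, _ in seq]
        probes = [0.0] + [
            (a + b) / 2 for a, b in zip(cps, cps[1:])
        ] + [cps[-1] + 1.0]
        for cp in probes:
            alpha = cp * root_risk
            pruned = prune_at(tree, cp)
            mine = _branch_risk(pruned.root) + alpha * pruned.n_leaves()
            optimum = min(r + alpha * l for r, l in all_subtrees)
            assert mine == pytest.approx(optimum, abs=1e-9)

    def test_sizes_decrease_as_cp_increases(self):
        X, y = random_classification_data(9, n=150, p=4, shift=1.0)
        tree = grow_tree(X, y, list("abcd"), minsplit=10, minbucket=3)
        seq = cost_complexity_sequence(tree)
        cps = [cp for cp, _ in seq]
        sizes = [s for _, s in seq]
        assert cps == sorted(cps)
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 1


class TestCrossValidation:
    def test_separable_data_has_near_zero_xerror(self):
        X, y = random_classification_data(10, n=100, shift=8.0)
        tree, profile = cross_validate(X, y, ["a", "b", "c"], seed=1,
                                       minsplit=10, minbucket=3)
        assert profile.xerror.min() == pytest.approx(0.0, abs=1e-12)

    def test_training_error_nonincreasing_with_tree_size(self):
        X, y = random_classification_data(11, n=150, p=4, shift=1.0)
        _, profile = cross_validate(X, y, list("abcd"), seed=2,
                                    minsplit=10, minbucket=3)
        # rows are ordered by increasing cp = decreasing size
        assert np.all(np.diff(profile.rel_error) >= -1e-12)

    def test_same_seed_identical_profile(self):
        X, y = random_classification_data(12, n=90, shift=1.0)
        _, p1 = cross_validate(X, y, ["a", "b", "c"], seed=5)
        _, p2 = cross_validate(X, y, ["a", "b", "c"], seed=5)
        np.testing.assert_array_equal(p1.xerror, p2.xerror)
        np.testing.assert_array_equal(p1.xstd, p2.xstd)

    def test_random_labels_give_relative_error_near_one(self):
        """Null simulation: with labels independent of the covariates,
        cross-validation finds no structure at any tree size.

        xerror is normalized by the *in-sample* root risk, which
        underestimates the population trivial error by O(sqrt(n)) counts
        (E|Binomial(n,1/2) - n/2| ~ 0.4*sqrt(n)), so the null expectation
        of xerror sits slightly above 1; for n = 60 that bias bound is
        0.4*sqrt(60)/(30 - 0.4*sqrt(60)) ~ 0.115."""
        reps = 200
        full, best = np.empty(reps), np.empty(reps)
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            X = rng.normal(size=(60, 2))
            y = rng.integers(0, 2, size=60)
            if len(np.unique(y)) < 2:  # pragma: no cover
                y[0] = 1 - y[0]
            _, profile = cross_validate(X, y, ["a", "b"], seed=r,
                                        minsplit=10, minbucket=3)
            full[r] = profile.xerror[0]
            best[r] = profile.xerror.min()
        se = full.std(ddof=1) / np.sqrt(reps)
        assert 1.0 - 3.3 * se <= full.mean() <= 1.115 + 3.3 * se
        # no tree size looks genuinely better than the trivial classifier
        assert best.mean() > 0.85


class TestPrune1SE:
    def make_tree(self):
        X, y = random_classification_data(13, n=120, p=4, shift=1.2)
        return grow_tree(X, y, list("abcd"), minsplit=15, minbucket=5)

    def fake_profile(self, cp, xerror, xstd, sizes):
        return CvProfile(
            cp=np.asarray(cp, dtype=float),
            n_leaves=np.asarray(sizes),
            rel_error=np.asarray(xerror),
            xerror=np.asarray(xerror, dtype=float),
            xstd=np.asarray(xstd, dtype=float),
            n_folds=10,
            seed=0,
        )

    def test_monotone_profile_keeps_full_tree(self):
        tree = self.make_tree()
        seq = cost_complexity_sequence(tree)
        cps = [c for c, _ in seq]
        prof = self.fake_profile(
            cps, np.linspace(1.0, 0.2, len(cps))[::-1], [1e-9] * len(cps),
            [s for _, s in seq],
        )
        pruned = prune_1se(tree, prof)
        # retains the cp=0 row, i.e. the largest tree in the sequence
        assert pruned.n_leaves() == seq[0][1]
        assert pruned.n_leaves() == max(s for _, s in seq)

    def test_flat_profile_selects_root(self):
        tree = self.make_tree()
        seq = cost_complexity_sequence(tree)
        cps = [c for c, _ in seq]
        prof = self.fake_profile(cps, [0.5] * len(cps), [0.05] * len(cps),
                                 [s for _, s in seq])
        assert prune_1se(tree, prof).root.is_leaf

    def test_hand_computed_selection(self):
        tree = self.make_tree()
        prof = self.fake_profile(
            [0.0, 0.05, 0.2], [1.0, 0.6, 0.9], [0.1, 0.15, 0.1], [5, 3, 1]
        )
        # min xerror 0.6 at cp=0.05; 1-SE threshold 0.75 excludes both others
        pruned = prune_1se(tree, prof)
        assert pruned.params["pruned_cp"] == pytest.approx(0.05)


class TestVariableImportance:
    def test_single_split_without_surrogates_is_100pct(self):
        rng = np.random.default_rng(14)
        X = np.column_stack([np.r_[rng.normal(0, 1, 30), rng.normal(5, 1, 30)],
                             rng.normal(size=60)])
        y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
        tree = grow_tree(X, y, ["signal", "noise"], minsplit=60, minbucket=20)
        assert len(tree.internal_nodes()) == 1
        imp = variable_importance(tree)
        sig = imp.set_index("variable")["importance_pct"]
        if len(tree.root.surrogates) == 0:
            assert sig["signal"] == pytest.approx(100.0)
        assert sig["signal"] > sig.get("noise", 0.0)

    def test_bookkeeping_matches_independent_recomputation(self):
        X, y = random_classification_data(15, n=150, p=4, shift=1.3)
        tree = grow_tree(X, y, list("abcd"), minsplit=20, minbucket=7)
        assert len(tree.internal_nodes()) >= 2
        credit = dict.fromkeys(tree.variables, 0.0)
        for node in tree.internal_nodes():
            imp = node.split.decrease * node.n
            credit[node.split.variable] += imp
            for s in node.surrogates:
                credit[s.variable] += s.adj_agreement * imp
        total = sum(credit.values())
        expected = {v: 100 * c / total for v, c in credit.items()}
        got = variable_importance(tree).set_index("variable")["importance_pct"]
        for v, pct in expected.items():
            assert got.get(v, 0.0) == pytest.approx(pct, abs=1e-9)

    def test_global_importance_sums_to_100_and_flags_rule(self):
        X, y = random_classification_data(16, n=150, p=5, shift=1.3)
        tree = grow_tree(X, y, list("abcde"), minsplit=20, minbucket=7)
        imp = variable_importance(tree)
        assert imp["importance_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        for row in imp.itertuples():
            assert row.significant == (row.importance_pct > 100 / 5)

    def test_split_scope_restricts_to_one_node(self):
        X, y = random_classification_data(17, n=150, p=4, shift=1.2)
        tree = grow_tree(X, y, list("abcd"), minsplit=15, minbucket=5)
        assert len(tree.internal_nodes()) >= 2
        imp1 = variable_importance(tree, scope=1)
        assert imp1["importance_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        root = tree.root
        top = imp1.iloc[0]
        assert top["variable"] == root.split.variable


class TestClassificationSummary:
    def test_all_correct(self):
        X, y = random_classification_data(18, n=60, shift=8.0)
        tree = grow_tree(X, y, ["a", "b", "c"], minsplit=4, minbucket=1)
        clades = np.repeat(["c1", "c2"], 30)
        cs = classification_summary(tree, X, y, clades)
        assert cs.percent() == 100.0
        assert cs.percent("c1") == 100.0

    def test_counts_and_percents(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["a", "a", "b", "b"])
        tree = grow_tree(X, y, ["x"], minsplit=2, minbucket=1)
        cs = classification_summary(tree, X, np.array(["a", "b", "b", "b"]),
                                    np.array(["c1", "c1", "c2", "c2"]))
        assert cs.overall[1] == 4
        assert 0 <= cs.percent() <= 100


def test_root_split_matches_rpart_oracle(tmp_path):
    """Independent check of the Gini machinery against R's rpart on a
    fixture: same primary root split variable, threshold and improvement."""
    rng = np.random.default_rng(19)
    n = 150
    X = np.round(rng.normal(size=(n, 4)), 3)
    y = ((X[:, 1] + 0.5 * X[:, 3] + rng.normal(0, 0.8, n)) > 0).astype(int)
    df = pd.DataFrame(X, columns=["v1", "v2", "v3", "v4"])
    df["y"] = np.where(y == 1, "pos", "neg")
    csv = tmp_path / "fixture.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(textwrap.dedent(f"""
        library(rpart)
        d <- read.csv("{csv}")
        d$y <- factor(d$y)
        fit <- rpart(y ~ ., data = d, method = "class",
                     control = rpart.control(cp = 0, minsplit = 20,
                                             minbucket = 7, xval = 0,
                                             maxcompete = 0, maxsurrogate = 0))
        s <- fit$splits
        cat(rownames(s)[1], s[1, "index"], s[1, "improve"], sep = ",")
    """))
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
    )
    assert out.returncode == 0, out.stderr
    var, thr, improve = out.stdout.strip().split(",")
    tree = grow_tree(X, y, ["v1", "v2", "v3", "v4"], minsplit=20, minbucket=7)
    root = tree.root.split
    assert root.variable == var
    assert root.threshold == pytest.approx(float(thr), rel=1e-6)
    assert root.decrease * tree.root.n == pytest.approx(float(improve), rel=1e-6)
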