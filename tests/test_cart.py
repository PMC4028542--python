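import json

import numpy as np
import pytest

from emgfi.cart import (
    CVConfig,
    DecisionTree,
    GrowthParams,
    PrunePoint,
    PruneSequence,
    TreeNode,
    _stratified_folds,
    cross_validate,
    export_tree,
    grow_tree,
    import_tree,
    prune_path,
    resubstitution_cost,
    select_tree,
)
from emgfi.core import CLASSES, FEATURE_NAMES, ValidationError

from _oracles import (
    dict_leaves,
    dict_risk,
    dict_shape,
    grow_brute,
    optimal_pruned_subtree,
    predict_json_brute,
    tree_to_dicts,
)

TWO = ("control", "neurogenic")


def random_cohort(seed, n, d=3, k=2, feature_names=None, classes=None):
    rng = np.random.default_rng(seed)
    classes = classes or CLASSES[:k]
    feature_names = feature_names or FEATURE_NAMES[:d]
    X = np.round(rng.normal(0, 1, (n, d)), 2)
    y = [classes[i] for i in rng.integers(0, k, n)]
    return X, y, feature_names, classes


class TestGrow:
    def test_perfect_single_split(self):
        X = np.array([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]])
        y = ["control"] * 3 + ["neurogenic"] * 3
        tree = grow_tree(X, y, GrowthParams(min_split=2), feature_names=("RMS1R",), classes=TWO)
        assert tree.n_decision_nodes == 1
        assert tree.n_terminal_nodes == 2
        assert resubstitution_cost(tree) == 0.0

    def test_identical_features_mixed_labels_single_leaf(self):
        X = np.ones((8, 2))
        y = ["control"] * 5 + ["neurogenic"] * 3
        tree = grow_tree(X, y, GrowthParams(min_split=2), feature_names=FEATURE_NAMES[:2], classes=TWO)
        assert tree.root.is_leaf
        assert tree.predict_one([1.0, 1.0]) == "control"

    def test_single_class_cohort_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        tree = grow_tree(X, ["myogenic"] * 10, feature_names=FEATURE_NAMES[:2])
        assert tree.root.is_leaf

    def test_missing_values_rejected(self):
        X = np.ones((6, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            grow_tree(X, ["control"] * 6, feature_names=FEATURE_NAMES[:2])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration_small_cohorts(self, seed):
        """Full-tree growth equals the brute-force recursive grower on n <= 12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(2, 5))
        X, y, names, classes = random_cohort(seed + 100, n, d=3, k=k)
        params = GrowthParams(min_leaf=1, min_split=2, max_depth=6)
        ours = grow_tree(X, y, params, feature_names=names, classes=classes)
        brute = grow_brute(X, y, classes, min_leaf=1, min_split=2, max_depth=6)
        assert dict_shape(tree_to_dicts(ours.root)) == dict_shape(brute)

    def test_counts_invariant_and_node_arithmetic(self):
        X, y, names, classes = random_cohort(5, 60, d=4, k=4, classes=CLASSES)
        tree = grow_tree(X, y, feature_names=names, classes=classes)
        tree.validate()  # children counts sum to parent; terminals = decisions + 1


class TestPrune:
    def test_single_leaf_sequence(self):
        tree = grow_tree(np.ones((6, 1)), ["control"] * 6, feature_names=("RMS1R",))
        path = prune_path(tree)
        assert len(path) == 1
        assert path.points[0].n_leaves == 1

    def test_last_element_is_majority_root(self):
        X, y, names, classes = random_cohort(7, 50, d=3, k=3, classes=CLASSES[:3])
        tree = grow_tree(X, y, GrowthParams(min_split=2), feature_names=names, classes=classes)
        path = prune_path(tree)
        last = path.points[-1]
        assert last.n_leaves == 1
        # majority with ties broken by canonical class order, like the tree
        majority = classes[int(np.argmax([y.count(c) for c in classes]))]
        assert last.tree.predict_one([0.0, 0.0, 0.0]) == majority

    def test_sequence_invariants_on_random_cohorts(self):
        for seed in range(6):
            X, y, names, classes = random_cohort(seed, 80, d=4, k=4, classes=CLASSES)
            tree = grow_tree(X, y, feature_names=names, classes=classes)
            path = prune_path(tree)  # PruneSequence validates monotonicity on build
            sizes = [p.n_leaves for p in path]
            assert sizes[0] == tree.n_terminal_nodes or sizes[0] <= tree.n_terminal_nodes
            assert sizes[-1] == 1

    def test_matches_exhaustive_subtree_search_40_points(self):
        """Each sequence element is the smallest optimal pruned subtree at its alpha."""
        X, y, names, classes = random_cohort(13, 40, d=3, k=3, classes=CLASSES[:3])
        params = GrowthParams(min_leaf=1, min_split=5, max_depth=5)
        tree = grow_tree(X, y, params, feature_names=names, classes=classes)
        path = prune_path(tree)
        full = tree_to_dicts(tree.root)
        n = len(y)
        alphas = [p.alpha for p in path.points]
        probes = []
        for k in range(len(alphas)):
            hi = alphas[k + 1] if k + 1 < len(alphas) else alphas[k] + 1.0
            probes.append((k, (alphas[k] + hi) / 2.0))
            probes.append((k, alphas[k]))
        for k, alpha in probes:
            best = optimal_pruned_subtree(full, alpha, n)
            ours = path.points[k]
            assert len(dict_leaves(best)) == ours.n_leaves
            assert dict_risk(best, n) == pytest.approx(ours.resubstitution_cost, abs=1e-12)
            assert dict_shape(best) == dict_shape(tree_to_dicts(ours.tree.root))


def make_strict_binary(n_decision):
    """A left-comb tree with the requested number of decision nodes."""
    leaf = lambda: TreeNode(class_counts=np.array([1, 0, 0, 0]))
    node = leaf()
    for i in range(n_decision):
        right = TreeNode(class_counts=np.array([0, 1, 0, 0]))
        parent = TreeNode(
            class_counts=node.class_counts + right.class_counts,
            feature=0,
            threshold=float(i),
            left=node,
            right=right,
        )
        node = parent
    return DecisionTree(root=node)


class TestTreeShape:
    @pytest.mark.parametrize("n_decision,n_terminal", [(11, 12), (5, 6), (7, 8), (0, 1)])
    def test_terminals_equal_decisions_plus_one(self, n_decision, n_terminal):
        tree = make_strict_binary(n_decision)
        tree.validate()
        assert tree.n_decision_nodes == n_decision
        assert tree.n_terminal_nodes == n_terminal


class TestCrossValidation:
    def test_deterministic_under_seed(self):
        X, y, names, classes = random_cohort(21, 80, d=4, k=4, classes=CLASSES)
        a = cross_validate(X, y, cv=CVConfig(seed=3), feature_names=names, classes=classes)
        b = cross_validate(X, y, cv=CVConfig(seed=3), feature_names=names, classes=classes)
        assert [p.cv_cost for p in a] == [p.cv_cost for p in b]
        assert [p.alpha for p in a] == [p.alpha for p in b]
        codes = np.array([CLASSES.index(c) for c in y])
        f1 = _stratified_folds(codes, 10, True, 3)
        f2 = _stratified_folds(codes, 10, True, 3)
        assert np.array_equal(f1, f2)

    def test_stratified_folds_balance_classes(self):
        codes = np.repeat(np.arange(4), 50)
        folds = _stratified_folds(codes, 10, True, 0)
        for v in range(10):
            counts = np.bincount(codes[folds == v], minlength=4)
            assert np.all(counts == 5)

    def test_separable_cohort_low_cv_cost(self):
        rng = np.random.default_rng(17)
        n = 120
        X = np.zeros((n, 2))
        y = []
        for i, cls in enumerate(TWO):
            X[i * 60 : (i + 1) * 60, 0] = rng.normal(3.0 * i, 0.3, 60)
            y += [cls] * 60
        X[:, 1] = rng.normal(0, 1, n)
        path = cross_validate(X, y, cv=CVConfig(seed=1), feature_names=FEATURE_NAMES[:2], classes=TWO)
        assert min(p.cv_cost for p in path) <= 0.05

    def test_random_labels_near_chance(self):
        # 4 balanced classes with permuted labels: CV cost ~ 0.75;
        # n = 400 gives a binomial SE of ~0.022, band is +/- 3.5 SE
        rng = np.random.default_rng(23)
        n = 400
        X = rng.normal(0, 1, (n, 4))
        y = [CLASSES[i % 4] for i in range(n)]
        rng.shuffle(y)
        path = cross_validate(
            X, y, cv=CVConfig(seed=2), feature_names=FEATURE_NAMES[:4]
        )
        best = min(p.cv_cost for p in path)
        assert 0.67 <= best <= 0.83

    def test_v_larger_than_n_rejected(self):
        X, y, names, classes = random_cohort(1, 5, d=2, k=2)
        with pytest.raises(ValidationError):
            cross_validate(X, y, cv=CVConfig(V=10), feature_names=names, classes=classes)


def synthetic_path(entries):
    """Build a PruneSequence fixture from (alpha, n_leaves, cv, se) tuples."""
    points = []
    resub = 0.0
    for alpha, n_leaves, cv, se in entries:
        leaf_tree = DecisionTree(root=TreeNode(class_counts=np.array([1, 0, 0, 0])))
        points.append(
            PrunePoint(
                alpha=alpha, tree=leaf_tree, n_leaves=n_leaves,
                resubstitution_cost=resub, cv_cost=cv, cv_cost_se=se,
            )
        )
        resub += 0.01
    return PruneSequence(points=points)


class TestSelection:
    def test_smallest_tree_wins_every_policy_when_also_cheapest(self):
        path = synthetic_path([(0.0, 5, 0.30, 0.02), (0.1, 2, 0.10, 0.02), (0.5, 1, 0.10, 0.02)])
        for policy in ("min_cost", "min_nodes", "balanced"):
            assert select_tree(path, policy) is not None
        # the minimum is shared by the 2-leaf and 1-leaf trees: ties go small
        chosen = [p for p in path.points if p.cv_cost == 0.10][-1]
        assert chosen.n_leaves == 1

    def test_monotone_trade_off_fixture(self):
        path = synthetic_path(
            [(0.0, 10, 0.10, 0.015), (0.01, 5, 0.11, 0.015), (0.05, 2, 0.19, 0.015), (0.2, 1, 0.40, 0.02)]
        )
        # min_cost: the 10-leaf tree; balanced: within 1 SE -> 5 leaves;
        # min_nodes: within +0.10 -> 2 leaves
        min_cost = select_tree(path, "min_cost")
        assert path.points[0].cv_cost == min(p.cv_cost for p in path.points)
        balanced_pick = [p for p in path.points if p.cv_cost <= 0.10 + 0.015][-1]
        assert balanced_pick.n_leaves == 5
        nodes_pick = [p for p in path.points if p.cv_cost <= 0.10 + 0.10][-1]
        assert nodes_pick.n_leaves == 2

    def test_policies_produce_non_increasing_sizes(self, small_labeled_cohort):
        df = small_labeled_cohort
        X = df[list(FEATURE_NAMES)].to_numpy()
        y = df["label"].tolist()
        path = cross_validate(X, y, cv=CVConfig(seed=11))
        sizes = [
            select_tree(path, policy).n_decision_nodes
            for policy in ("min_cost", "balanced", "min_nodes")
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_selection_reproducible(self, small_labeled_cohort):
        df = small_labeled_cohort
        X = df[list(FEATURE_NAMES)].to_numpy()
        y = df["label"].tolist()
        t1 = select_tree(cross_validate(X, y, cv=CVConfig(seed=4)), "balanced")
        t2 = select_tree(cross_validate(X, y, cv=CVConfig(seed=4)), "balanced")
        assert export_tree(t1) == export_tree(t2)

    def test_missing_cv_costs_rejected(self):
        X, y, names, classes = random_cohort(2, 30, d=2, k=2)
        path = prune_path(grow_tree(X, y, feature_names=names, classes=classes))
        with pytest.raises(ValidationError):
            select_tree(path, "min_cost")


class TestPredict:
    def test_boundary_goes_left(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = ["control", "control", "neurogenic", "neurogenic"]
        tree = grow_tree(X, y, GrowthParams(min_split=2), feature_names=("RMS1R",), classes=TWO)
        thr = tree.root.threshold
        assert tree.predict_one([thr]) == "control"

    def test_missing_routing_feature_rejected(self):
        X = np.array([[0.0, 5.0], [1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        y = ["control", "control", "neurogenic", "neurogenic"]
        tree = grow_tree(X, y, GrowthParams(min_split=2), feature_names=FEATURE_NAMES[:2], classes=TWO)
        with pytest.raises(ValidationError, match="routing"):
            tree.predict_one([np.nan, 5.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_recursive_descent_oracle(self, seed):
        X, y, names, classes = random_cohort(seed, 60, d=4, k=4, classes=CLASSES)
        tree = grow_tree(X, y, feature_names=names, classes=classes)
        doc = json.loads(export_tree(tree))
        probes = np.random.default_rng(seed + 1).normal(0, 1.5, (40, 4))
        for x in probes:
            assert tree.predict_one(x) == predict_json_brute(
                doc["root"], list(names), list(classes), x
            )


class TestExport:
    def test_json_round_trip_identical_structure(self):
        X, y, names, classes = random_cohort(3, 50, d=4, k=3, classes=CLASSES[:3])
        tree = grow_tree(X, y, feature_names=names, classes=classes)
        back = import_tree(export_tree(tree, "json"))
        assert dict_shape(tree_to_dicts(back.root)) == dict_shape(tree_to_dicts(tree.root))
        assert export_tree(back) == export_tree(tree)

    def test_dot_has_all_nodes(self):
        tree = make_strict_binary(7)
        dot = export_tree(tree, "dot")
        assert dot.count("fillcolor") == 15  # 7 decision + 8 terminal
        assert dot.count("#f4cccc") == 8  # terminal styling distinct from decision
        assert dot.count("#cfe2f3") == 7

    def test_text_render_one_split(self):
        X = np.array([[0.0], [1.0]])
        tree = grow_tree(X, ["control", "neurogenic"], GrowthParams(min_split=2),
                         feature_names=("RMS1R",), classes=TWO)
        text = export_tree(tree, "text")
        assert "RMS1R <= 0.5?" in text
        assert "yes: -> control" in text
        assert "no:  -> neurogenic" in text

    def test_unknown_format_rejected(self):
        tree = make_strict_binary(1)
        with pytest.raises(ValidationError):
            export_tree(tree, "xml")


class TestSklearnCrossCheck:
    def test_resubstitution_accuracy_matches_reference_library(self):
        """Same stopping rules: our resubstitution accuracy should match sklearn's."""
        sklearn = pytest.importorskip("sklearn.tree")
        X, y, names, classes = random_cohort(31, 150, d=4, k=4, classes=CLASSES)
        params = GrowthParams(min_leaf=1, min_split=5, max_depth=10)
        ours = grow_tree(X, y, params, feature_names=names, classes=classes)
        clf = sklearn.DecisionTreeClassifier(
            criterion="gini", min_samples_split=5, min_samples_leaf=1,
            max_depth=10, random_state=0,
        ).fit(X, y)
        ours_acc = 1.0 - resubstitution_cost(ours)
        ref_acc = clf.score(X, y)
        assert ours_acc == pytest.approx(ref_acc, abs=0.02)
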