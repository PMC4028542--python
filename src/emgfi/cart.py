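"""Classification trees: Gini growth, cost-complexity pruning, V-fold CV.

This is a self-contained CART engine for the 4-class etiology problem
(control / neurogenic / myogenic / idiopathic) over the 12 RMS/MF features.
Conventions, fixed for determinism and documented in every export:

* splits are axis-aligned, ``feature <= threshold`` routes left;
* candidate thresholds are midpoints between consecutive distinct sorted
  feature values;
* equal impurity decrease is broken by lowest feature index, then lowest
  threshold;
* majority ties in a leaf are broken by the canonical class order.

Pruning follows minimal cost-complexity (weakest-link) pruning: the nested
subtree sequence T_0 > T_1 > ... > {root} with breakpoints
``alpha_k = (R(t) - R(T_t)) / (|leaves(T_t)| - 1)``, where R is the
resubstitution misclassification cost.  Cross-validation scores each
interval's representative ``alpha' = sqrt(alpha_k * alpha_{k+1})`` by growing
and pruning a tree per fold, and three selection policies pick the final
subtree: minimum CV cost, minimum node count within a cost ceiling, or the
1-SE compromise between cost and size.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import CLASSES, FEATURE_NAMES, ValidationError

_TIE_TOL = 1e-12

TREE_SCHEMA = "emgfi-tree/1"


@dataclass
class GrowthParams:
    """Stopping and admissibility rules for tree growth.

    Defaults suit the small-cohort regime (~100 subjects): nodes with fewer
    than ``min_split`` samples are not split, children must contain at least
    ``min_leaf`` samples, and growth stops at ``max_depth``.
    """

    min_leaf: int = 1
    min_split: int = 5
    max_depth: int = 10

    def __post_init__(self):
        if self.min_leaf < 1 or self.min_split < 2 or self.max_depth < 1:
            raise ValidationError("invalid growth parameters")


@dataclass
class CVConfig:
    """V-fold cross-validation settings (V=10 by default, stratified, seeded)."""

    V: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.V < 2:
            raise ValidationError("V must be at least 2")


@dataclass
class TreeNode:
    class_counts: np.ndarray  # (n_classes,) training counts reaching the node
    feature: int | None = None  # None => terminal node
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n_samples(self) -> int:
        return int(np.sum(self.class_counts))

    @property
    def predicted_class_index(self) -> int:
        # argmax with ties broken by canonical class order
        return int(np.argmax(self.class_counts))

    def validate(self) -> None:
        if self.is_leaf:
            if self.left is not None or self.right is not None:
                raise ValidationError("terminal node must have no children")
        else:
            if self.left is None or self.right is None:
                raise ValidationError("decision node must have two children")
            child_sum = self.left.class_counts + self.right.class_counts
            if not np.array_equal(child_sum, self.class_counts):
                raise ValidationError("decision node counts must equal the sum of its children")
            self.left.validate()
            self.right.validate()


@dataclass
class DecisionTree:
    root: TreeNode
    feature_names: tuple[str, ...] = FEATURE_NAMES
    classes: tuple[str, ...] = CLASSES
    params: GrowthParams | None = None
    selection_policy: str | None = None
    seed: int | None = None

    def validate(self) -> None:
        self.root.validate()
        if self.n_terminal_nodes != self.n_decision_nodes + 1:
            raise ValidationError("binary tree must satisfy terminals = decisions + 1")

    def _count(self, leaf: bool) -> int:
        total = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                total += leaf
            else:
                total += not leaf
                stack.extend([node.left, node.right])
        return total

    @property
    def n_decision_nodes(self) -> int:
        return self._count(leaf=False)

    @property
    def n_terminal_nodes(self) -> int:
        return self._count(leaf=True)

    def predict_one(self, x: Mapping[str, float] | Sequence[float]) -> str:
        if isinstance(x, Mapping):
            missing = [n for n in self.feature_names if n not in x]
            vec = np.array(
                [x.get(n, np.nan) for n in self.feature_names], dtype=float
            )
        else:
            vec = np.asarray(x, dtype=float)
            if vec.shape != (len(self.feature_names),):
                raise ValidationError(
                    f"expected {len(self.feature_names)} features, got shape {vec.shape}"
                )
        node = self.root
        while not node.is_leaf:
            v = vec[node.feature]
            if not np.isfinite(v):
                raise ValidationError(
                    f"feature {self.feature_names[node.feature]!r} needed on the routing"
                    " path is missing or non-finite"
                )
            node = node.left if v <= node.threshold else node.right
        return self.classes[node.predicted_class_index]

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return np.array([self.predict_one(X)])
        return np.array([self.predict_one(row) for row in X])


@dataclass
class PrunePoint:
    alpha: float
    tree: DecisionTree
    n_leaves: int
    resubstitution_cost: float
    cv_cost: float | None = None
    cv_cost_se: float | None = None


@dataclass
class PruneSequence:
    """Minimal cost-complexity sequence, most complex subtree first."""

    points: list[PrunePoint]

    def __post_init__(self):
        if not self.points:
            raise ValidationError("empty prune sequence")
        alphas = [p.alpha for p in self.points]
        sizes = [p.n_leaves for p in self.points]
        resub = [p.resubstitution_cost for p in self.points]
        if any(a2 <= a1 for a1, a2 in zip(alphas, alphas[1:])):
            raise ValidationError("alphas must be strictly increasing")
        if any(s2 > s1 for s1, s2 in zip(sizes, sizes[1:])):
            raise ValidationError("subtree sizes must be non-increasing")
        if any(r2 < r1 - _TIE_TOL for r1, r2 in zip(resub, resub[1:])):
            raise ValidationError("resubstitution cost must be non-decreasing")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


def _encode_labels(y: Sequence[str], classes: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[label] for label in y], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"label {exc.args[0]!r} outside the class set {classes}") from exc


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(
    X: np.ndarray, codes: np.ndarray, n_classes: int, min_leaf: int
) -> tuple[float, int, float] | None:
    """Return (impurity decrease, feature, threshold) of the best admissible split.

    Ties on impurity decrease resolve to the lowest feature index, then the
    lowest threshold.  Returns None when no split has positive decrease.
    """
    n = X.shape[0]
    parent_counts = np.bincount(codes, minlength=n_classes)
    parent_gini = _gini(parent_counts)
    best: tuple[float, int, float] | None = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), codes[order]] = 1.0
        cum = np.cumsum(onehot, axis=0)
        cut = np.nonzero(xs[:-1] < xs[1:])[0]  # split between positions i and i+1
        if cut.size == 0:
            continue
        nl = cut + 1
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        cut, nl, nr = cut[ok], nl[ok], nr[ok]
        if cut.size == 0:
            continue
        left = cum[cut]
        right = parent_counts[None, :] - left
        gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        decrease = parent_gini - (nl * gini_l + nr * gini_r) / n
        top = float(np.max(decrease))
        if top <= _TIE_TOL:
            continue
        # lowest threshold among the within-feature ties
        cand = cut[decrease >= top - _TIE_TOL]
        i = int(cand[0])
        thr = float((xs[i] + xs[i + 1]) / 2.0)
        if best is None or top > best[0] + _TIE_TOL:
            best = (top, f, thr)
    return best


def grow_tree(
    X,
    y: Sequence[str],
    params: GrowthParams | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    classes: tuple[str, ...] = CLASSES,
) -> DecisionTree:
    """Greedy Gini tree over midpoint thresholds; deterministic by construction."""
    params = params or GrowthParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValidationError(f"X must be (n, {len(feature_names)}), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains missing or non-finite values")
    codes = _encode_labels(y, classes)
    if codes.shape[0] != X.shape[0]:
        raise ValidationError("X and y length mismatch")
    n_classes = len(classes)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(codes[idx], minlength=n_classes)
        node = TreeNode(class_counts=counts)
        if (
            np.count_nonzero(counts) <= 1
            or idx.size < params.min_split
            or depth >= params.max_depth
        ):
            return node
        found = _best_split(X[idx], codes[idx], n_classes, params.min_leaf)
        if found is None:
            return node
        _, f, thr = found
        go_left = X[idx, f] <= thr
        node.feature = f
        node.threshold = thr
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    tree = DecisionTree(
        root=build(np.arange(X.shape[0]), 0),
        feature_names=tuple(feature_names),
        classes=tuple(classes),
        params=params,
    )
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# cost-complexity pruning


def _node_risk(node: TreeNode, n_total: int) -> float:
    """Resubstitution cost contribution if ``node`` were a leaf (unit costs)."""
    return float(node.n_samples - node.class_counts[node.predicted_class_index]) / n_total


def _subtree_risk_leaves(node: TreeNode, n_total: int) -> tuple[float, int]:
    if node.is_leaf:
        return _node_risk(node, n_total), 1
    rl, ll = _subtree_risk_leaves(node.left, n_total)
    rr, lr = _subtree_risk_leaves(node.right, n_total)
    return rl + rr, ll + lr


def resubstitution_cost(tree: DecisionTree) -> float:
    """Fraction of training samples misclassified by the tree."""
    n_total = tree.root.n_samples
    risk, _ = _subtree_risk_leaves(tree.root, n_total)
    return risk


def _collapse(node: TreeNode) -> None:
    node.feature = None
    node.threshold = None
    node.left = None
    node.right = None


def _weakest_links(root: TreeNode, n_total: int) -> dict[int, tuple[TreeNode, float]]:
    """Map id(node) -> (node, g(t)) for every internal node."""
    links: dict[int, tuple[TreeNode, float]] = {}

    def visit(node: TreeNode):
        if node.is_leaf:
            return
        sub_risk, leaves = _subtree_risk_leaves(node, n_total)
        g = (_node_risk(node, n_total) - sub_risk) / (leaves - 1)
        links[id(node)] = (node, g)
        visit(node.left)
        visit(node.right)

    visit(root)
    return links


def prune_path(tree: DecisionTree) -> PruneSequence:
    """Weakest-link pruning: the nested sequence of cost-complexity optima.

    Each point's tree minimises ``resub_cost + alpha * n_leaves`` for every
    alpha in ``[alpha_k, alpha_{k+1})``; the last point is the root leaf.
    """
    work = copy.deepcopy(tree)
    n_total = work.root.n_samples
    if n_total == 0:
        raise ValidationError("cannot prune a tree with no training samples")

    def snapshot(alpha: float) -> PrunePoint:
        t = copy.deepcopy(work)
        t.selection_policy = tree.selection_policy
        risk, leaves = _subtree_risk_leaves(t.root, n_total)
        return PrunePoint(alpha=alpha, tree=t, n_leaves=leaves, resubstitution_cost=risk)

    def prune_at(g_cut: float) -> None:
        # collapse every internal node whose g is minimal; recompute until none
        while True:
            links = _weakest_links(work.root, n_total)
            hits = [node for node, g in links.values() if g <= g_cut + _TIE_TOL]
            if not hits:
                return
            for node in hits:
                if not node.is_leaf:  # may already be inside a collapsed subtree
                    _collapse(node)

    points: list[PrunePoint] = []
    # T(0): collapse links that do not reduce resubstitution cost at all
    if _weakest_links(work.root, n_total):
        prune_at(0.0)
    points.append(snapshot(0.0))

    while not work.root.is_leaf:
        links = _weakest_links(work.root, n_total)
        g_min = min(g for _, g in links.values())
        prune_at(g_min)
        alpha = max(g_min, 0.0)
        point = snapshot(alpha)
        if alpha <= points[-1].alpha + _TIE_TOL:
            points[-1] = point  # degenerate tie: keep the smaller subtree
        else:
            points.append(point)
    return PruneSequence(points=points)


def _subtree_for_alpha(path: PruneSequence, alpha: float) -> DecisionTree:
    chosen = path.points[0]
    for p in path.points:
        if p.alpha <= alpha + _TIE_TOL:
            chosen = p
    return chosen.tree


def _stratified_folds(codes: np.ndarray, V: int, stratified: bool, seed: int) -> np.ndarray:
    """Deterministic fold assignment; stratification deals each class round-robin."""
    n = codes.shape[0]
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if stratified:
        start = 0
        for c in np.unique(codes):
            idx = np.flatnonzero(codes == c)
            rng.shuffle(idx)
            fold[idx] = (np.arange(idx.size) + start) % V
            start = (start + idx.size) % V
    else:
        perm = rng.permutation(n)
        fold[perm] = np.arange(n) % V
    return fold


def cross_validate(
    X,
    y: Sequence[str],
    params: GrowthParams | None = None,
    cv: CVConfig | None = None,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    classes: tuple[str, ...] = CLASSES,
) -> PruneSequence:
    """Master prune path with V-fold cross-validated cost per pruning level.

    For each interval of the master path, the representative penalty is the
    geometric mean of its endpoints; each fold grows and prunes its own tree,
    and the held-out misclassification costs are pooled over all subjects.
    The standard error is the binomial ``sqrt(c (1 - c) / n)``.
    """
    params = params or GrowthParams()
    cv = cv or CVConfig()
    X = np.asarray(X, dtype=float)
    y = list(y)
    n = X.shape[0]
    if cv.V > n:
        raise ValidationError(f"V={cv.V} exceeds the number of samples ({n})")
    codes = _encode_labels(y, classes)

    master_tree = grow_tree(X, y, params, feature_names, classes)
    path = prune_path(master_tree)
    alphas = [p.alpha for p in path.points]
    rep_alphas = []
    for k in range(len(alphas)):
        if k + 1 < len(alphas):
            rep_alphas.append(float(np.sqrt(max(alphas[k], 0.0) * alphas[k + 1])))
        else:
            rep_alphas.append(np.inf)

    fold = _stratified_folds(codes, cv.V, cv.stratified, cv.seed)
    loss = np.zeros((len(rep_alphas), n))
    y_arr = np.asarray(y)
    for v in range(cv.V):
        test = fold == v
        train = ~test
        if not np.any(test):
            continue
        fold_tree = grow_tree(X[train], y_arr[train], params, feature_names, classes)
        fold_path = prune_path(fold_tree)
        for k, a in enumerate(rep_alphas):
            sub = _subtree_for_alpha(fold_path, a)
            pred = sub.predict(X[test])
            loss[k, test] = pred != y_arr[test]

    for k, point in enumerate(path.points):
        c = float(np.mean(loss[k]))
        point.cv_cost = c
        point.cv_cost_se = float(np.sqrt(max(c * (1.0 - c), 0.0) / n))
    return path


SELECTION_POLICIES = ("min_cost", "min_nodes", "balanced")


def select_tree(
    path: PruneSequence, policy: str, min_nodes_cost_ceiling: float = 0.10
) -> DecisionTree:
    """Pick the final subtree from a cross-validated prune sequence.

    ``min_cost``
        the subtree with minimal CV cost; ties go to the smaller tree.
    ``min_nodes``
        the smallest subtree whose CV cost stays within
        ``min_nodes_cost_ceiling`` (absolute) above the minimum.
    ``balanced``
        the 1-SE rule: the largest alpha whose CV cost is within one standard
        error of the minimum.
    """
    if policy not in SELECTION_POLICIES:
        raise ValidationError(f"unknown selection policy {policy!r}; use {SELECTION_POLICIES}")
    points = path.points
    if any(p.cv_cost is None for p in points):
        raise ValidationError("prune sequence lacks cross-validated costs; run cross_validate")
    best = min(points, key=lambda p: p.cv_cost)
    # last point attaining the minimum = fewest leaves (sizes are non-increasing)
    best = [p for p in points if p.cv_cost <= best.cv_cost + _TIE_TOL][-1]
    if policy == "min_cost":
        chosen = best
    elif policy == "balanced":
        ceiling = best.cv_cost + best.cv_cost_se
        chosen = [p for p in points if p.cv_cost <= ceiling + _TIE_TOL][-1]
    else:  # min_nodes
        ceiling = best.cv_cost + min_nodes_cost_ceiling
        chosen = [p for p in points if p.cv_cost <= ceiling + _TIE_TOL][-1]
    tree = copy.deepcopy(chosen.tree)
    tree.selection_policy = policy
    tree.validate()
    return tree


def fit_tree(
    X,
    y: Sequence[str],
    policy: str = "min_cost",
    params: GrowthParams | None = None,
    cv: CVConfig | None = None,
    min_nodes_cost_ceiling: float = 0.10,
) -> tuple[DecisionTree, PruneSequence]:
    """Grow, cross-validate and select in one call; returns (tree, path)."""
    path = cross_validate(X, y, params=params, cv=cv)
    tree = select_tree(path, policy, min_nodes_cost_ceiling)
    tree.seed = (cv or CVConfig()).seed
    return tree, path


# ---------------------------------------------------------------------------
# export / import


def _node_to_dict(node: TreeNode, feature_names) -> dict:
    d: dict = {"class_counts": [int(c) for c in node.class_counts]}
    if not node.is_leaf:
        d["feature"] = feature_names[node.feature]
        d["threshold"] = float(node.threshold)
        d["left"] = _node_to_dict(node.left, feature_names)
        d["right"] = _node_to_dict(node.right, feature_names)
    return d


def _node_from_dict(d: dict, feature_index: Mapping[str, int]) -> TreeNode:
    node = TreeNode(class_counts=np.asarray(d["class_counts"], dtype=int))
    if "feature" in d:
        node.feature = feature_index[d["feature"]]
        node.threshold = float(d["threshold"])
        node.left = _node_from_dict(d["left"], feature_index)
        node.right = _node_from_dict(d["right"], feature_index)
    return node


def export_tree(tree: DecisionTree, fmt: str = "json") -> str:
    """Serialise a tree to ``json`` (lossless), ``dot`` (Graphviz) or ``text``."""
    if fmt == "json":
        doc = {
            "schema": TREE_SCHEMA,
            "classes": list(tree.classes),
            "feature_names": list(tree.feature_names),
            "selection_policy": tree.selection_policy,
            "seed": tree.seed,
            "convention": "feature <= threshold routes left; class ties break in class order",
            "root": _node_to_dict(tree.root, tree.feature_names),
        }
        return json.dumps(doc, indent=2)
    if fmt == "dot":
        return _to_dot(tree)
    if fmt == "text":
        return _to_text(tree)
    raise ValidationError(f"unknown export format {fmt!r}; use json, dot or text")


def import_tree(document: str) -> DecisionTree:
    doc = json.loads(document)
    if doc.get("schema") != TREE_SCHEMA:
        raise ValidationError(f"unrecognised tree schema {doc.get('schema')!r}")
    feature_names = tuple(doc["feature_names"])
    index = {n: i for i, n in enumerate(feature_names)}
    tree = DecisionTree(
        root=_node_from_dict(doc["root"], index),
        feature_names=feature_names,
        classes=tuple(doc["classes"]),
        selection_policy=doc.get("selection_policy"),
        seed=doc.get("seed"),
    )
    tree.validate()
    return tree


def _counts_bar(node: TreeNode, classes) -> str:
    return " ".join(f"{c[:2]}:{int(n)}" for c, n in zip(classes, node.class_counts))


def _to_dot(tree: DecisionTree) -> str:
    lines = [
        "digraph classification_tree {",
        '  node [shape=box, style="filled,rounded"];',
    ]
    counter = [0]

    def walk(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        bar = _counts_bar(node, tree.classes)
        if node.is_leaf:
            cls = tree.classes[node.predicted_class_index]
            lines.append(f'  n{nid} [label="{cls}\\n{bar}", fillcolor="#f4cccc"];')
        else:
            name = tree.feature_names[node.feature]
            lines.append(
                f'  n{nid} [label="{name} <= {node.threshold:.6g}\\n{bar}", fillcolor="#cfe2f3"];'
            )
            lid = walk(node.left)
            rid = walk(node.right)
            lines.append(f'  n{nid} -> n{lid} [label="yes"];')
            lines.append(f'  n{nid} -> n{rid} [label="no"];')
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)


def _to_text(tree: DecisionTree) -> str:
    out: list[str] = []

    def walk(node: TreeNode, indent: int, prefix: str):
        pad = "  " * indent
        if node.is_leaf:
            cls = tree.classes[node.predicted_class_index]
            out.append(f"{pad}{prefix}-> {cls} [{_counts_bar(node, tree.classes)}]")
        else:
            name = tree.feature_names[node.feature]
            out.append(f"{pad}{prefix}{name} <= {node.threshold:.6g}?")
            walk(node.left, indent + 1, "yes: ")
            walk(node.right, indent + 1, "no:  ")

    walk(tree.root, 0, "")
    return "\n".join(out)
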