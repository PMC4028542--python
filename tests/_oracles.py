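"""Independent brute-force reference implementations used only by the tests.

Everything here is written with plain loops, separate from the package's
vectorised code paths, so agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np


def rms_brute(trace) -> float:
    total = 0.0
    for a in trace:
        total += float(a) * float(a)
    return (total / len(trace)) ** 0.5


def median_frequency_brute(freqs, power, band) -> float:
    """Cumulative-sum scan with linear interpolation in the crossing bin."""
    fs, ps = [], []
    for f, p in zip(freqs, power):
        if band[0] <= f <= band[1]:
            fs.append(float(f))
            ps.append(float(p))
    total = sum(ps)
    assert total > 0
    half = total / 2.0
    cum = 0.0
    for k in range(len(ps)):
        prev = cum
        cum += ps[k]
        if cum >= half:
            if k == 0:
                return fs[0]
            if cum == prev:
                return fs[k]
            return fs[k - 1] + (half - prev) / (cum - prev) * (fs[k] - fs[k - 1])
    return fs[-1]


def gini_brute(labels, classes) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    out = 1.0
    for c in classes:
        p = sum(1 for y in labels if y == c) / n
        out -= p * p
    return out


def enumerate_splits(X, y, classes, min_leaf=1):
    """All admissible (feature, midpoint-threshold) splits with their Gini decrease."""
    n, d = X.shape
    parent = gini_brute(y, classes)
    out = []
    for f in range(d):
        values = sorted(set(X[:, f]))
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2.0
            left = [y[i] for i in range(n) if X[i, f] <= thr]
            right = [y[i] for i in range(n) if X[i, f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            dec = parent - (
                len(left) * gini_brute(left, classes) + len(right) * gini_brute(right, classes)
            ) / n
            out.append((dec, f, thr))
    return out


def best_split_brute(X, y, classes, min_leaf=1, tol=1e-12):
    """Best split under the package's tie rule: lowest feature, lowest threshold."""
    splits = enumerate_splits(X, y, classes, min_leaf)
    if not splits:
        return None
    top = max(dec for dec, _, _ in splits)
    if top <= tol:
        return None
    ties = [(f, thr) for dec, f, thr in splits if dec >= top - tol]
    return min(ties)


def grow_brute(X, y, classes, min_leaf=1, min_split=2, max_depth=10, depth=0):
    """Reference recursive grower; returns nested dicts mirroring the tree."""
    counts = [sum(1 for lab in y if lab == c) for c in classes]
    node = {"counts": counts}
    n = len(y)
    n_present = sum(1 for c in counts if c > 0)
    if n_present <= 1 or n < min_split or depth >= max_depth:
        return node
    found = best_split_brute(X, y, classes, min_leaf)
    if found is None:
        return node
    f, thr = found
    li = [i for i in range(n) if X[i, f] <= thr]
    ri = [i for i in range(n) if X[i, f] > thr]
    node["feature"] = f
    node["threshold"] = thr
    node["left"] = grow_brute(X[li], [y[i] for i in li], classes, min_leaf, min_split, max_depth, depth + 1)
    node["right"] = grow_brute(X[ri], [y[i] for i in ri], classes, min_leaf, min_split, max_depth, depth + 1)
    return node


def tree_to_dicts(node, feature_names=None):
    """Convert a package TreeNode to the oracle's nested-dict shape."""
    d = {"counts": [int(c) for c in node.class_counts]}
    if not node.is_leaf:
        d["feature"] = int(node.feature)
        d["threshold"] = float(node.threshold)
        d["left"] = tree_to_dicts(node.left)
        d["right"] = tree_to_dicts(node.right)
    return d


def enumerate_pruned_subtrees(node):
    """Every subtree obtainable by collapsing internal nodes of ``node``.

    Yields nested dicts {counts, [feature, threshold, left, right]}.
    """
    collapsed = {"counts": list(node["counts"])}
    if "feature" not in node:
        return [collapsed]
    out = [collapsed]
    for left in enumerate_pruned_subtrees(node["left"]):
        for right in enumerate_pruned_subtrees(node["right"]):
            out.append(
                {
                    "counts": list(node["counts"]),
                    "feature": node["feature"],
                    "threshold": node["threshold"],
                    "left": left,
                    "right": right,
                }
            )
    return out


def dict_leaves(node):
    if "feature" not in node:
        return [node]
    return dict_leaves(node["left"]) + dict_leaves(node["right"])


def dict_risk(node, n_total):
    """Resubstitution misclassification cost of a dict tree (unit costs)."""
    total = 0
    for leaf in dict_leaves(node):
        total += sum(leaf["counts"]) - max(leaf["counts"])
    return total / n_total


def dict_shape(node):
    """Hashable structural signature (feature, threshold, children)."""
    if "feature" not in node:
        return ("leaf", tuple(node["counts"]))
    return (
        node["feature"],
        round(node["threshold"], 12),
        dict_shape(node["left"]),
        dict_shape(node["right"]),
    )


def optimal_pruned_subtree(full_dict, alpha, n_total):
    """Smallest pruned subtree minimising cost + alpha * n_leaves (brute force)."""
    best = None
    for sub in enumerate_pruned_subtrees(full_dict):
        leaves = len(dict_leaves(sub))
        obj = dict_risk(sub, n_total) + alpha * leaves
        key = (round(obj, 12), leaves)
        if best is None or key < best[0]:
            best = (key, sub)
    return best[1]


def predict_json_brute(doc_root, feature_names, classes, x):
    """Recursive-descent prediction straight off the exported JSON document."""
    node = doc_root
    while "feature" in node:
        idx = feature_names.index(node["feature"])
        node = node["left"] if x[idx] <= node["threshold"] else node["right"]
    counts = node["class_counts"]
    return classes[counts.index(max(counts))]
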