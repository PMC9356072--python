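"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's tree-building path: the split
oracle enumerates every (feature, midpoint) candidate and scores it by the
weighted child error directly, so it can certify the splits chosen by the
fitted trees.
"""

from __future__ import annotations

import numpy as np

REL_TOL = 1e-9


def weighted_sse(y: np.ndarray, w: np.ndarray) -> float:
    """Sum_i w_i (y_i - weighted mean)^2, computed directly."""
    W = w.sum()
    mu = (w * y).sum() / W
    return float((w * (y - mu) ** 2).sum())


def node_impurity(y: np.ndarray, w: np.ndarray) -> float:
    """Weighted variance (weighted MSE against the weighted mean)."""
    return weighted_sse(y, w) / w.sum()


def enumerate_splits(X: np.ndarray, y: np.ndarray, w: np.ndarray, min_leaf: int):
    """All feasible (feature, threshold, left-index-tuple, child error) candidates.

    Thresholds are midpoints between consecutive distinct sorted values;
    feasibility requires min_leaf samples on each side. The child error is
    sum_c W_c * impurity_c = sum of the two weighted SSEs, whose argmin is
    the split maximizing the weighted-MSE improvement (the ancestor term is
    constant within a node).
    """
    n, p = X.shape
    out = []
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        for i in range(n - 1):
            if xs[i] == xs[i + 1]:
                continue
            thr = (xs[i] + xs[i + 1]) / 2.0
            left = X[:, j] <= thr
            nl = int(left.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            err = weighted_sse(y[left], w[left]) + weighted_sse(y[~left], w[~left])
            out.append((j, thr, tuple(np.flatnonzero(left)), err))
    return out


def best_split_partitions(X, y, w, min_leaf):
    """The set of left-member partitions achieving the minimal child error."""
    cands = enumerate_splits(X, y, w, min_leaf)
    if not cands:
        return set()
    best = min(c[3] for c in cands)
    tol = REL_TOL * max(1.0, abs(best))
    return {c[2] for c in cands if c[3] <= best + tol}


def build_oracle_tree(X, y, w, min_leaf, idx=None):
    """Recursively grown brute-force tree; nodes carry member index tuples."""
    if idx is None:
        idx = np.arange(X.shape[0])
    node = {"members": tuple(idx)}
    if idx.size < 2 * min_leaf or node_impurity(y[idx], w[idx]) <= 1e-15:
        return node
    parts = best_split_partitions(X[idx], y[idx], w[idx], min_leaf)
    if not parts:
        return node
    left_local = np.array(next(iter(parts)), dtype=int)
    mask = np.zeros(idx.size, dtype=bool)
    mask[left_local] = True
    node["left"] = build_oracle_tree(X, y, w, min_leaf, idx[mask])
    node["right"] = build_oracle_tree(X, y, w, min_leaf, idx[~mask])
    return node


def fitted_tree_partitions(tree, X_boot):
    """Walk an AnnotatedTree and yield (member indices, left-member indices)
    for every internal node, membership taken over the bootstrap rows."""
    leaf_assign = {}
    results = []

    def recurse(v, members):
        if tree.children_left[v] == -1:
            return
        left_mask = X_boot[members, tree.feature[v]] <= tree.threshold[v]
        left = members[left_mask]
        right = members[~left_mask]
        results.append((tuple(members), tuple(left)))
        recurse(tree.children_left[v], left)
        recurse(tree.children_right[v], right)

    recurse(0, np.arange(X_boot.shape[0]))
    return results
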