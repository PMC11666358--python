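"""Exact path-dependent Shapley values for decision-tree ensembles.

Implements the polynomial-time tree-Shapley recursion (the "path-dependent"
feature perturbation: absent features are marginalized over the tree's own
training cover). For every sample x and tree, phi satisfies the efficiency
axiom exactly:

    base + sum_k phi_k = f(x),  base = cover-weighted mean leaf value.

The recursion maintains, per path from the root, the set of distinct split
features with their "zero" (cover) and "one" (decision) fractions and a
vector of permutation weights; EXTEND adds a feature to the path, UNWIND
removes one, and at each leaf every path feature receives its weighted
contribution. Complexity O(leaves * depth^2) per sample and tree. The DFS is
iterative (per-depth path buffers) so it JIT-compiles with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _extend(pd_, pz, po, pw, length, pzero, pone, pindex):
    pd_[length] = pindex
    pz[length] = pzero
    po[length] = pone
    pw[length] = 1.0 if length == 0 else 0.0
    for i in range(length - 1, -1, -1):
        pw[i + 1] += pone * pw[i] * (i + 1.0) / (length + 1.0)
        pw[i] = pzero * pw[i] * (length - i) / (length + 1.0)
    return length + 1


@njit(cache=False)
def _unwind(pd_, pz, po, pw, length, i):
    l = length - 1
    one = po[i]
    zero = pz[i]
    n = pw[l]
    for j in range(l - 1, -1, -1):
        if one != 0.0:
            t = pw[j]
            pw[j] = n * (l + 1.0) / ((j + 1.0) * one)
            n = t - pw[j] * zero * (l - j) / (l + 1.0)
        else:
            pw[j] = pw[j] * (l + 1.0) / (zero * (l - j))
    for j in range(i, l):
        pd_[j] = pd_[j + 1]
        pz[j] = pz[j + 1]
        po[j] = po[j + 1]
    return length - 1


@njit(cache=False)
def _unwound_sum(pd_, pz, po, pw, length, i):
    l = length - 1
    one = po[i]
    zero = pz[i]
    total = 0.0
    if one != 0.0:
        n = pw[l]
        for j in range(l - 1, -1, -1):
            tmp = n * (l + 1.0) / ((j + 1.0) * one)
            total += tmp
            n = pw[j] - tmp * zero * (l - j) / (l + 1.0)
    else:
        for j in range(l - 1, -1, -1):
            total += pw[j] * (l + 1.0) / (zero * (l - j))
    return total


@njit(cache=False)
def _tree_shap_sample(
    children_left, children_right, feature, threshold, cover, value, x, phi, max_depth
):
    depth_cap = max_depth + 2
    # per-level path buffers; level l owns a path of length <= l + 1
    pd_ = np.empty((depth_cap, depth_cap), dtype=np.int64)
    pz = np.empty((depth_cap, depth_cap), dtype=np.float64)
    po = np.empty((depth_cap, depth_cap), dtype=np.float64)
    pw = np.empty((depth_cap, depth_cap), dtype=np.float64)
    plen = np.zeros(depth_cap, dtype=np.int64)

    # DFS stack: node, level, pzero, pone, pindex
    cap = 4 * depth_cap + 4
    st_node = np.empty(cap, dtype=np.int64)
    st_level = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_pi = np.empty(cap, dtype=np.int64)
    sp = 0
    st_node[sp] = 0
    st_level[sp] = 0
    st_pz[sp] = 1.0
    st_po[sp] = 1.0
    st_pi[sp] = -1
    sp += 1

    while sp > 0:
        sp -= 1
        node = st_node[sp]
        level = st_level[sp]
        pzero = st_pz[sp]
        pone = st_po[sp]
        pindex = st_pi[sp]

        if level == 0:
            length = 0
        else:
            parent_len = plen[level - 1]
            for k in range(parent_len):
                pd_[level, k] = pd_[level - 1, k]
                pz[level, k] = pz[level - 1, k]
                po[level, k] = po[level - 1, k]
                pw[level, k] = pw[level - 1, k]
            length = parent_len
        length = _extend(pd_[level], pz[level], po[level], pw[level], length, pzero, pone, pindex)

        if children_left[node] < 0:  # leaf
            v = value[node]
            for i in range(1, length):
                w = _unwound_sum(pd_[level], pz[level], po[level], pw[level], length, i)
                phi[pd_[level, i]] += w * (po[level, i] - pz[level, i]) * v
            plen[level] = length
            continue

        split = feature[node]
        left = children_left[node]
        right = children_right[node]
        if x[split] <= threshold[node]:
            hot, cold = left, right
        else:
            hot, cold = right, left

        iz = 1.0
        io = 1.0
        k_found = -1
        for i in range(1, length):
            if pd_[level, i] == split:
                k_found = i
                break
        if k_found >= 0:
            iz = pz[level, k_found]
            io = po[level, k_found]
            length = _unwind(pd_[level], pz[level], po[level], pw[level], length, k_found)
        plen[level] = length

        r_node = cover[node]
        # push cold first so hot is processed first (order irrelevant)
        st_node[sp] = cold
        st_level[sp] = level + 1
        st_pz[sp] = iz * cover[cold] / r_node
        st_po[sp] = 0.0
        st_pi[sp] = split
        sp += 1
        st_node[sp] = hot
        st_level[sp] = level + 1
        st_pz[sp] = iz * cover[hot] / r_node
        st_po[sp] = io
        st_pi[sp] = split
        sp += 1


@njit(cache=False)
def _tree_shap_matrix(
    children_left, children_right, feature, threshold, cover, value, X, out, max_depth
):
    for s in range(X.shape[0]):
        _tree_shap_sample(
            children_left, children_right, feature, threshold, cover, value,
            X[s], out[s], max_depth,
        )


def tree_shap_values(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for one fitted sklearn regression tree.

    Returns (phi, base) with phi of shape (n_samples, n_features) and base
    the tree's expected value (cover-weighted leaf mean = root value).
    """
    t = tree.tree_
    # sklearn predicts in float32; mirror the cast so threshold comparisons
    # route every sample to the same leaf the tree itself would use
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float32), dtype=np.float64)
    value = np.ascontiguousarray(t.value.reshape(-1), dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    _tree_shap_matrix(
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
        value,
        X,
        phi,
        int(t.max_depth),
    )
    return phi, float(value[0])


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for a fitted sklearn RandomForestRegressor
    (the forest prediction is the mean over trees, so phi averages too)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    base = 0.0
    for est in forest.estimators_:
        p, b = tree_shap_values(est, X)
        phi += p
        base += b
    n = len(forest.estimators_)
    return phi / n, base / n


# ---------------------------------------------------------------------------
# brute-force reference (exponential; for small trees and tests)
# ---------------------------------------------------------------------------

def expected_value_conditioned(tree_arrays, x: np.ndarray, subset: frozenset) -> float:
    """E[f(x)] when only the features in ``subset`` are known, marginalizing
    the rest over the tree's training cover (path-dependent conditioning)."""
    children_left, children_right, feature, threshold, cover, value = tree_arrays

    def recurse(node: int) -> float:
        if children_left[node] < 0:
            return value[node]
        f = feature[node]
        left, right = children_left[node], children_right[node]
        if f in subset:
            nxt = left if x[f] <= threshold[node] else right
            return recurse(nxt)
        wl = cover[left] / cover[node]
        return wl * recurse(left) + (1.0 - wl) * recurse(right)

    return recurse(0)


def brute_force_tree_shap(tree, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exhaustive Shapley enumeration over all feature coalitions of one tree
    (only features the tree actually splits on matter)."""
    from itertools import combinations
    from math import factorial

    t = tree.tree_
    x = np.asarray(x, dtype=np.float32).astype(np.float64)  # sklearn predicts in float32
    arrays = (
        t.children_left, t.children_right, t.feature, t.threshold,
        t.weighted_n_node_samples, t.value.reshape(-1),
    )
    used = sorted({int(f) for f in t.feature if f >= 0})
    m = len(used)
    phi = np.zeros(n_features)
    cache: dict[frozenset, float] = {}

    def val(s: frozenset) -> float:
        if s not in cache:
            cache[s] = expected_value_conditioned(arrays, x, s)
        return cache[s]

    for k in used:
        others = [f for f in used if f != k]
        total = 0.0
        for size in range(m):
            w = factorial(size) * factorial(m - size - 1) / factorial(m)
            for combo in combinations(others, size):
                s = frozenset(combo)
                total += w * (val(s | {k}) - val(s))
        phi[k] = total
    return phi
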