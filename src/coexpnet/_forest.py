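"""Numba random-forest regression importances for small observation counts.

Network inference fits one ensemble per target gene over thousands of
targets, each with only tens of observations; generic tree libraries spend
more time on per-tree bookkeeping than on the splits themselves. This
implementation compiles the whole forest loop.

Semantics: CART regression trees, variance-reduction splits, bootstrap rows,
k random candidate features per node (ties between equally good splits go to
the earliest candidate in the shuffled draw order). The importance credited
to feature f is the sum over nodes split on f of
(node samples / n) * impurity decrease, averaged over trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _tree_accumulate(X, y, idx, k, max_depth, perm, imp):
    """Grow one tree over rows ``idx`` (bootstrap indices); add its
    per-feature weighted impurity decreases into ``imp``."""
    n_total = idx.size
    p = X.shape[1]

    # manual stack of (start, end, depth) over segments of idx
    cap = 4 * n_total + 8
    st_start = np.empty(cap, np.int64)
    st_end = np.empty(cap, np.int64)
    st_depth = np.empty(cap, np.int64)
    top = 0
    st_start[top] = 0
    st_end[top] = n_total
    st_depth[top] = 0
    top += 1

    xs = np.empty(n_total, np.float64)
    ys = np.empty(n_total, np.float64)
    buf_l = np.empty(n_total, np.int64)
    buf_r = np.empty(n_total, np.int64)

    while top > 0:
        top -= 1
        start = st_start[top]
        end = st_end[top]
        depth = st_depth[top]
        m = end - start

        s1 = 0.0
        s2 = 0.0
        for i in range(start, end):
            v = y[idx[i]]
            s1 += v
            s2 += v * v
        node_imp = s2 / m - (s1 / m) ** 2
        if m < 2 or node_imp <= 1e-15 or (max_depth >= 0 and depth >= max_depth):
            continue

        # k distinct candidate features by partial Fisher-Yates; perm stays
        # a permutation across calls so the draw is uniform.
        for j in range(k):
            r = j + np.random.randint(p - j)
            tmp = perm[j]
            perm[j] = perm[r]
            perm[r] = tmp

        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        for j in range(k):
            f = perm[j]
            for i in range(m):
                xs[i] = X[idx[start + i], f]
                ys[i] = y[idx[start + i]]
            order = np.argsort(xs[:m], kind="mergesort")
            # prefix scan over sorted order
            left_s1 = 0.0
            left_s2 = 0.0
            for c in range(m - 1):
                v = ys[order[c]]
                left_s1 += v
                left_s2 += v * v
                if xs[order[c]] >= xs[order[c + 1]]:
                    continue
                ml = c + 1
                mr = m - ml
                right_s1 = s1 - left_s1
                right_s2 = s2 - left_s2
                imp_l = left_s2 / ml - (left_s1 / ml) ** 2
                imp_r = right_s2 / mr - (right_s1 / mr) ** 2
                gain = node_imp - (ml * imp_l + mr * imp_r) / m
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (xs[order[c]] + xs[order[c + 1]])

        if best_f < 0:
            continue

        imp[best_f] += (m / n_total) * best_gain

        # stable partition of idx[start:end] on the chosen split
        nl = 0
        nr = 0
        for i in range(start, end):
            if X[idx[i], best_f] <= best_thr:
                buf_l[nl] = idx[i]
                nl += 1
            else:
                buf_r[nr] = idx[i]
                nr += 1
        for i in range(nl):
            idx[start + i] = buf_l[i]
        for i in range(nr):
            idx[start + nl + i] = buf_r[i]

        st_start[top] = start
        st_end[top] = start + nl
        st_depth[top] = depth + 1
        top += 1
        st_start[top] = start + nl
        st_end[top] = end
        st_depth[top] = depth + 1
        top += 1


@njit(cache=True)
def forest_importances(X, y, n_trees, k, max_depth, bootstrap, seed):
    """Mean per-feature importance over ``n_trees`` trees.

    X: (n_obs, p) float64; y: (n_obs,) float64; max_depth < 0 = unlimited.
    Deterministic given ``seed``.
    """
    np.random.seed(seed)
    n, p = X.shape
    total = np.zeros(p)
    imp = np.zeros(p)
    perm = np.arange(p)
    idx = np.empty(n, np.int64)
    for _ in range(n_trees):
        if bootstrap:
            for i in range(n):
                idx[i] = np.random.randint(n)
        else:
            for i in range(n):
                idx[i] = i
        imp[:] = 0.0
        _tree_accumulate(X, y, idx, k, max_depth, perm, imp)
        total += imp
    return total / n_trees
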