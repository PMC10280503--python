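"""Numba kernels for CART-style tree growth and traversal.

Split search is exhaustive over midpoints of sorted unique feature values,
scored by Gini impurity; ties are broken toward the lowest feature index and
then the lowest threshold (candidate features are scanned in increasing
index order and thresholds in increasing order, so the first strictly-best
candidate wins).  All randomness (bootstrap resampling, feature
subsampling) comes from numba's per-thread legacy RNG seeded explicitly per
tree, which makes tree growth bit-reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def grow_tree(X, y, n_classes, max_depth, min_leaf, mtry, seed, bootstrap):
    """Grow one tree; returns (feature, threshold, left, right, counts) arrays.

    feature[i] == -1 marks a leaf.  counts[i] holds the class histogram of
    the (bootstrap) training rows that reached node i.
    """
    n, F = X.shape
    np.random.seed(seed)
    order = np.empty(n, np.int64)
    if bootstrap:
        for i in range(n):
            order[i] = np.random.randint(0, n)
    else:
        for i in range(n):
            order[i] = i

    max_nodes = 2 * n + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    counts = np.zeros((max_nodes, n_classes), np.int64)

    featbuf = np.empty(F, np.int64)
    vals = np.empty(n)
    tmpbuf = np.empty(n, np.int64)

    stack = [(0, 0, n, 0)]
    n_nodes = 1
    while len(stack) > 0:
        node, s, e, depth = stack.pop()
        m = e - s
        for i in range(s, e):
            counts[node, y[order[i]]] += 1
        pure = False
        for c in range(n_classes):
            if counts[node, c] == m:
                pure = True
        if pure or depth >= max_depth or m < 2 * min_leaf:
            continue

        # sample mtry candidate features without replacement (partial Fisher-Yates)
        for f in range(F):
            featbuf[f] = f
        for f in range(mtry):
            j = f + np.random.randint(0, F - f)
            tmp = featbuf[f]
            featbuf[f] = featbuf[j]
            featbuf[j] = tmp
        sel = np.sort(featbuf[:mtry])

        best_imp = 1e300
        best_f = -1
        best_t = 0.0
        for fi in range(mtry):
            f = sel[fi]
            for i in range(m):
                vals[i] = X[order[s + i], f]
            o = np.argsort(vals[:m])
            lc = np.zeros(n_classes, np.int64)
            rc = counts[node].copy()
            for i in range(m - 1):
                c = y[order[s + o[i]]]
                lc[c] += 1
                rc[c] -= 1
                if vals[o[i + 1]] <= vals[o[i]]:
                    continue  # not a boundary between distinct values
                nl = i + 1
                nr = m - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                gl = 0.0
                gr = 0.0
                for c2 in range(n_classes):
                    gl += lc[c2] * lc[c2]
                    gr += rc[c2] * rc[c2]
                # sum of child sizes times child Gini impurities
                imp = nl - gl / nl + nr - gr / nr
                t = 0.5 * (vals[o[i]] + vals[o[i + 1]])
                if imp < best_imp or (
                    imp == best_imp and (f < best_f or (f == best_f and t < best_t))
                ):
                    best_imp = imp
                    best_f = f
                    best_t = t
        if best_f < 0:
            continue  # no valid split (constant candidate features)

        nl = 0
        for i in range(m):
            if X[order[s + i], best_f] <= best_t:
                tmpbuf[nl] = order[s + i]
                nl += 1
        nr = nl
        for i in range(m):
            if X[order[s + i], best_f] > best_t:
                tmpbuf[nr] = order[s + i]
                nr += 1
        for i in range(m):
            order[s + i] = tmpbuf[i]

        feat[node] = best_f
        thr[node] = best_t
        left[node] = n_nodes
        right[node] = n_nodes + 1
        stack.append((n_nodes, s, s + nl, depth + 1))
        stack.append((n_nodes + 1, s + nl, e, depth + 1))
        n_nodes += 2

    return (feat[:n_nodes], thr[:n_nodes], left[:n_nodes], right[:n_nodes],
            counts[:n_nodes].copy())


@njit(cache=True)
def accumulate_leaf_freqs(feat, thr, left, right, counts, X, out):
    """Add each row's leaf class-frequency vector of one tree into ``out``."""
    n = X.shape[0]
    C = counts.shape[1]
    for i in range(n):
        node = 0
        while feat[node] >= 0:
            if X[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        tot = 0.0
        for c in range(C):
            tot += counts[node, c]
        for c in range(C):
            out[i, c] += counts[node, c] / tot
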