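"""Numba kernels for survival-tree growing and traversal.

The split search is the standard log-rank rule: at each node, ``mtry``
features are drawn without replacement and up to ``nsplit`` random
candidate cut points per feature are scored by the standardized two-sample
log-rank statistic |O - E| / sqrt(V) with the hypergeometric variance over
the pooled distinct event times.  A split must leave at least ``nodesize``
bootstrap members on each side and must have a strictly positive
statistic; otherwise the node becomes a leaf.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LEAF = -1


@njit(cache=True)
def logrank_statistic(time_sorted, event_sorted, mask_sorted):
    """Standardized log-rank statistic for a two-group split.

    Inputs are aligned arrays sorted by increasing time; ``mask_sorted``
    flags group-1 membership.  Censored observations tied with events at
    the same time are still at risk at that time (events first).  Returns
    0 when the variance is degenerate.
    """
    m = time_sorted.shape[0]
    n_risk = m
    n_risk_1 = 0
    for i in range(m):
        if mask_sorted[i]:
            n_risk_1 += 1
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < m:
        t = time_sorted[i]
        j = i
        d = 0
        d1 = 0
        while j < m and time_sorted[j] == t:
            if event_sorted[j]:
                d += 1
                if mask_sorted[j]:
                    d1 += 1
            j += 1
        if d > 0 and n_risk > 1:
            p = n_risk_1 / n_risk
            o_minus_e += d1 - d * p
            var += d * p * (1.0 - p) * (n_risk - d) / (n_risk - 1.0)
        for k in range(i, j):
            n_risk -= 1
            if mask_sorted[k]:
                n_risk_1 -= 1
        i = j
    if var <= 0.0:
        return 0.0
    return abs(o_minus_e) / np.sqrt(var)


@njit(cache=True)
def grow_tree(X, time, event, inbag, mtry, nodesize, nsplit, seed):
    """Grow one survival tree on the bootstrap sample ``inbag``.

    Returns (feature, threshold, left, right, n_nodes, work, node_of) where
    ``work`` is the in-bag index array permuted so each node's members are
    contiguous, and ``node_of[i]`` is the terminal node of ``work[i]``.
    Internal nodes have feature >= 0 and children indices; leaves have
    feature == -1.
    """
    np.random.seed(seed)
    m = inbag.shape[0]
    p = X.shape[1]
    max_nodes = 2 * m + 1
    feature = np.full(max_nodes, LEAF, np.int64)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    work = inbag.copy()
    node_of = np.full(m, -1, np.int64)

    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    top = 0
    n_nodes = 1
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = m
    top = 1

    feat_pool = np.empty(p, np.int64)
    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        msz = hi - lo

        n_events = 0
        for i in range(lo, hi):
            if event[work[i]]:
                n_events += 1

        best_stat = 0.0
        best_feat = -1
        best_thresh = 0.0
        if msz >= 2 * nodesize and n_events > 0:
            # node samples sorted by time (for the log-rank scan)
            t_node = np.empty(msz, np.float64)
            for i in range(msz):
                t_node[i] = time[work[lo + i]]
            order = np.argsort(t_node, kind="mergesort")
            t_sorted = np.empty(msz, np.float64)
            e_sorted = np.empty(msz, np.uint8)
            idx_sorted = np.empty(msz, np.int64)
            for i in range(msz):
                w = work[lo + order[i]]
                idx_sorted[i] = w
                t_sorted[i] = time[w]
                e_sorted[i] = event[w]

            for i in range(p):
                feat_pool[i] = i
            n_try = mtry if mtry < p else p
            mask = np.empty(msz, np.uint8)
            for k in range(n_try):
                r = k + np.random.randint(p - k)
                f = feat_pool[r]
                feat_pool[r] = feat_pool[k]
                feat_pool[k] = f
                # candidate thresholds: random member values below the max
                vmin = X[idx_sorted[0], f]
                vmax = vmin
                for i in range(1, msz):
                    v = X[idx_sorted[i], f]
                    if v < vmin:
                        vmin = v
                    if v > vmax:
                        vmax = v
                if vmax <= vmin:
                    continue
                for s in range(nsplit):
                    c = X[idx_sorted[np.random.randint(msz)], f]
                    if c >= vmax:
                        continue
                    n_left = 0
                    for i in range(msz):
                        go_left = X[idx_sorted[i], f] <= c
                        mask[i] = 1 if go_left else 0
                        if go_left:
                            n_left += 1
                    if n_left < nodesize or msz - n_left < nodesize:
                        continue
                    stat = logrank_statistic(t_sorted, e_sorted, mask)
                    if stat > best_stat:
                        best_stat = stat
                        best_feat = f
                        best_thresh = c

        if best_feat < 0:
            for i in range(lo, hi):
                node_of[i] = node
            continue

        # stable partition of work[lo:hi] on the winning split
        buf = np.empty(msz, np.int64)
        nl = 0
        for i in range(lo, hi):
            if X[work[i], best_feat] <= best_thresh:
                buf[nl] = work[i]
                nl += 1
        nr = nl
        for i in range(lo, hi):
            if X[work[i], best_feat] > best_thresh:
                buf[nr] = work[i]
                nr += 1
        for i in range(msz):
            work[lo + i] = buf[i]

        l_id = n_nodes
        r_id = n_nodes + 1
        n_nodes += 2
        feature[node] = best_feat
        threshold[node] = best_thresh
        left[node] = l_id
        right[node] = r_id
        stack_node[top] = l_id
        stack_lo[top] = lo
        stack_hi[top] = lo + nl
        top += 1
        stack_node[top] = r_id
        stack_lo[top] = lo + nl
        stack_hi[top] = hi
        top += 1

    return feature[:n_nodes], threshold[:n_nodes], left[:n_nodes], right[:n_nodes], n_nodes, work, node_of


@njit(cache=True)
def apply_tree(feature, threshold, left, right, X):
    """Terminal node index for every row of X."""
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = node
    return out


@njit(cache=True)
def leaf_hazards(node_of, work, time, event, leaf_nodes, grid):
    """Nelson-Aalen cumulative hazard of each leaf, evaluated on ``grid``.

    ``leaf_nodes`` is the sorted array of terminal node ids; row k of the
    result is H(grid) for leaf ``leaf_nodes[k]`` computed from its in-bag
    members.
    """
    n_leaves = leaf_nodes.shape[0]
    G = grid.shape[0]
    out = np.zeros((n_leaves, G), np.float64)
    m = work.shape[0]
    for k in range(n_leaves):
        node = leaf_nodes[k]
        cnt = 0
        for i in range(m):
            if node_of[i] == node:
                cnt += 1
        t = np.empty(cnt, np.float64)
        e = np.empty(cnt, np.uint8)
        j = 0
        for i in range(m):
            if node_of[i] == node:
                t[j] = time[work[i]]
                e[j] = event[work[i]]
                j += 1
        order = np.argsort(t, kind="mergesort")
        # Nelson-Aalen over the leaf's distinct event times
        h = 0.0
        g = 0
        i = 0
        n_risk = cnt
        while i < cnt:
            tt = t[order[i]]
            j2 = i
            d = 0
            while j2 < cnt and t[order[j2]] == tt:
                if e[order[j2]]:
                    d += 1
                j2 += 1
            if d > 0:
                while g < G and grid[g] < tt:
                    out[k, g] = h
                    g += 1
                h += d / n_risk
            n_risk -= j2 - i
            i = j2
        while g < G:
            out[k, g] = h
            g += 1
    return out
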