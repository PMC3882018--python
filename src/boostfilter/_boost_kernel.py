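"""Numba kernels for histogram-based boosted regression trees on 0/1/2 dosages.

The split search exploits the 3-valued genotype coding: a single pass over a
node's members accumulates, per SNP, the residual sum and member count in each
genotype class, after which both candidate split points (g < 0.5 and g < 1.5)
are scored in O(P). Child histograms are obtained by scanning the smaller
child and subtracting from the parent, so one tree costs O(N_bag * P) per
tree level in the worst case.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# A split must improve the node SSE by more than this fraction of the node's
# residual sum of squares; guards against accepting float-cancellation noise
# on (near-)constant residual nodes.
_REL_EPS = 1e-9


@njit(cache=True)
def _node_hist(G, idx, start, end, resid, s, c):
    """Accumulate per-SNP residual sums and counts by genotype class.

    Returns the node's residual sum of squares."""
    P = G.shape[1]
    for j in range(P):
        s[j, 0] = 0.0
        s[j, 1] = 0.0
        s[j, 2] = 0.0
        c[j, 0] = 0.0
        c[j, 1] = 0.0
        c[j, 2] = 0.0
    ss = 0.0
    for t in range(start, end):
        i = idx[t]
        r = resid[i]
        ss += r * r
        for j in range(P):
            g = G[i, j]
            s[j, g] += r
            c[j, g] += 1.0
    return ss


@njit(cache=True)
def _hist_subtract(s_parent, c_parent, s_child, c_child):
    P = s_parent.shape[0]
    for j in range(P):
        for g in range(3):
            s_parent[j, g] -= s_child[j, g]
            c_parent[j, g] -= c_child[j, g]


@njit(cache=True)
def _best_split_from_hist(s, c, ss, min_node):
    """Best (variable, split point index, improvement) for one node.

    Split point index 0 means threshold 0.5 ({0} vs {1,2}); 1 means 1.5
    ({0,1} vs {2}).  improvement = parent SSE - (left SSE + right SSE)
    = sum_L^2/n_L + sum_R^2/n_R - sum^2/n.  Ties keep the lowest SNP index,
    threshold 0.5 before 1.5.  Returns (-1, -1, 0.0) when no eligible split
    improves on the parent.
    """
    P = s.shape[0]
    best_j = -1
    best_t = -1
    best_imp = 0.0
    # total count/sum identical across SNPs; take from SNP 0
    n0 = c[0, 0] + c[0, 1] + c[0, 2]
    stot = s[0, 0] + s[0, 1] + s[0, 2]
    if n0 < 2 * min_node:
        return best_j, best_t, best_imp
    base = stot * stot / n0
    thresh = _REL_EPS * (ss if ss > 0.0 else 1.0)
    for j in range(P):
        # threshold 0.5: left = class 0
        sl = s[j, 0]
        nl = c[j, 0]
        if nl >= min_node and n0 - nl >= min_node:
            sr = stot - sl
            imp = sl * sl / nl + sr * sr / (n0 - nl) - base
            if imp > best_imp:
                best_imp = imp
                best_j = j
                best_t = 0
        # threshold 1.5: left = classes 0,1
        sl = s[j, 0] + s[j, 1]
        nl = c[j, 0] + c[j, 1]
        if nl >= min_node and n0 - nl >= min_node:
            sr = stot - sl
            imp = sl * sl / nl + sr * sr / (n0 - nl) - base
            if imp > best_imp:
                best_imp = imp
                best_j = j
                best_t = 1
    if best_imp <= thresh:
        return -1, -1, 0.0
    return best_j, best_t, best_imp


@njit(cache=True)
def _partition(G, idx, start, end, j, t, buf):
    """Stable partition of idx[start:end] on genotype class of SNP j.

    Members with dosage class <= t go left.  Returns the split position."""
    nl = 0
    nr = 0
    for q in range(start, end):
        i = idx[q]
        if G[i, j] <= t:
            idx[start + nl] = i
            nl += 1
        else:
            buf[nr] = i
            nr += 1
    for q in range(nr):
        idx[start + nl + q] = buf[q]
    return start + nl


@njit(cache=True)
def _node_ss(resid, idx, start, end):
    ss = 0.0
    for t in range(start, end):
        r = resid[idx[t]]
        ss += r * r
    return ss


@njit(cache=True)
def grow_tree(G, resid, idx, k, min_node,
              node_feat, node_thresh, node_left, node_right,
              node_value, node_imp,
              buf, S, C, leaf_node, leaf_start, leaf_end,
              leaf_bj, leaf_bt, leaf_bimp):
    """Best-first growth of one regression tree to at most ``k`` splits.

    ``idx`` holds the bag member indices (reordered in place).  Node arrays
    (capacity 2k+1) are written in place; terminal values are mean bag
    residuals.  The invariant maintained throughout is that open leaf ``L``
    owns histogram slot ``L`` of the workspaces ``S``/``C``.
    Returns the number of nodes allocated.
    """
    bag_n = idx.shape[0]
    node_feat[:] = -1
    node_imp[:] = 0.0
    node_value[:] = 0.0
    ss = _node_hist(G, idx, 0, bag_n, resid, S[0], C[0])
    bj, bt, bimp = _best_split_from_hist(S[0], C[0], ss, min_node)
    leaf_node[0] = 0
    leaf_start[0] = 0
    leaf_end[0] = bag_n
    leaf_bj[0] = bj
    leaf_bt[0] = bt
    leaf_bimp[0] = bimp
    n_leaves = 1
    next_node = 1
    for _split in range(k):
        # best-first: pick the open leaf whose best split improves most
        pick = -1
        pick_imp = 0.0
        for L in range(n_leaves):
            if leaf_bj[L] >= 0 and leaf_bimp[L] > pick_imp:
                pick_imp = leaf_bimp[L]
                pick = L
        if pick < 0:
            break
        j = leaf_bj[pick]
        t = leaf_bt[pick]
        start = leaf_start[pick]
        end = leaf_end[pick]
        nid = leaf_node[pick]
        mid = _partition(G, idx, start, end, j, t, buf)
        lid = next_node
        rid = next_node + 1
        next_node += 2
        node_feat[nid] = j
        node_thresh[nid] = 0.5 if t == 0 else 1.5
        node_left[nid] = lid
        node_right[nid] = rid
        node_imp[nid] = pick_imp
        # histogram slots: the smaller child is scanned into the free slot,
        # the parent slot is updated in place to hold the larger child
        free = n_leaves
        nl = mid - start
        nr = end - mid
        if nl <= nr:
            ss_l = _node_hist(G, idx, start, mid, resid, S[free], C[free])
            _hist_subtract(S[pick], C[pick], S[free], C[free])
            ss_r = _node_ss(resid, idx, mid, end)
            slot_l = free
        else:
            ss_r = _node_hist(G, idx, mid, end, resid, S[free], C[free])
            _hist_subtract(S[pick], C[pick], S[free], C[free])
            ss_l = _node_ss(resid, idx, start, mid)
            slot_l = pick
        slot_r = pick if slot_l == free else free
        bj_l, bt_l, bimp_l = _best_split_from_hist(S[slot_l], C[slot_l],
                                                   ss_l, min_node)
        bj_r, bt_r, bimp_r = _best_split_from_hist(S[slot_r], C[slot_r],
                                                   ss_r, min_node)
        # leaf slot_l <- left child, leaf slot_r <- right child, preserving
        # the leaf-owns-its-slot invariant
        leaf_node[slot_l] = lid
        leaf_start[slot_l] = start
        leaf_end[slot_l] = mid
        leaf_bj[slot_l] = bj_l
        leaf_bt[slot_l] = bt_l
        leaf_bimp[slot_l] = bimp_l
        leaf_node[slot_r] = rid
        leaf_start[slot_r] = mid
        leaf_end[slot_r] = end
        leaf_bj[slot_r] = bj_r
        leaf_bt[slot_r] = bt_r
        leaf_bimp[slot_r] = bimp_r
        n_leaves += 1
    # terminal values: mean bag residual per leaf
    for L in range(n_leaves):
        stot = S[L][0, 0] + S[L][0, 1] + S[L][0, 2]
        ntot = C[L][0, 0] + C[L][0, 1] + C[L][0, 2]
        node_value[leaf_node[L]] = stot / ntot if ntot > 0 else 0.0
    return next_node


@njit(cache=True)
def fit_boosted_trees(G, y, bags, k, nu, min_node,
                      node_feat, node_thresh, node_left, node_right,
                      node_value, node_imp, n_nodes, vim, F, resid):
    """Stochastic gradient boosting with squared-error loss.

    G : (n, P) int8 dosage classes in {0,1,2}
    bags : (M, bag_n) subject indices per tree (sampled without replacement)
    k : splits per tree (interaction depth); nu : shrinkage
    Written in place: per-tree node arrays (capacity 2k+1 each), cumulative
    variable importance ``vim`` (split improvements summed per SNP), model
    predictions ``F`` and residuals ``resid`` for all subjects.
    """
    n, P = G.shape
    M, bag_n = bags.shape
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    for i in range(n):
        F[i] = mu
        resid[i] = y[i] - mu

    idx = np.empty(bag_n, dtype=np.int64)
    buf = np.empty(bag_n, dtype=np.int64)
    S = np.zeros((k + 1, P, 3), dtype=np.float64)
    C = np.zeros((k + 1, P, 3), dtype=np.float64)
    leaf_node = np.empty(k + 1, dtype=np.int32)
    leaf_start = np.empty(k + 1, dtype=np.int64)
    leaf_end = np.empty(k + 1, dtype=np.int64)
    leaf_bj = np.empty(k + 1, dtype=np.int32)
    leaf_bt = np.empty(k + 1, dtype=np.int32)
    leaf_bimp = np.empty(k + 1, dtype=np.float64)

    for m in range(M):
        for q in range(bag_n):
            idx[q] = bags[m, q]
        n_nodes[m] = grow_tree(G, resid, idx, k, min_node,
                               node_feat[m], node_thresh[m], node_left[m],
                               node_right[m], node_value[m], node_imp[m],
                               buf, S, C, leaf_node, leaf_start, leaf_end,
                               leaf_bj, leaf_bt, leaf_bimp)
        for nd in range(n_nodes[m]):
            if node_feat[m, nd] >= 0:
                vim[node_feat[m, nd]] += node_imp[m, nd]
        # update model for all subjects (in- and out-of-bag)
        for i in range(n):
            nd = 0
            while node_feat[m, nd] >= 0:
                if G[i, node_feat[m, nd]] + 0.0 < node_thresh[m, nd]:
                    nd = node_left[m, nd]
                else:
                    nd = node_right[m, nd]
            v = nu * node_value[m, nd]
            F[i] += v
            resid[i] -= v


@njit(cache=True)
def predict_trees(G, node_feat, node_thresh, node_left, node_right,
                  node_value, nu, mu, out):
    n = G.shape[0]
    M = node_feat.shape[0]
    for i in range(n):
        acc = mu
        for m in range(M):
            nd = 0
            while node_feat[m, nd] >= 0:
                if G[i, node_feat[m, nd]] + 0.0 < node_thresh[m, nd]:
                    nd = node_left[m, nd]
                else:
                    nd = node_right[m, nd]
            acc += nu * node_value[m, nd]
        out[i] = acc
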