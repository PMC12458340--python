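"""Independent brute-force oracles used to validate the permutation machinery.

Everything here is deliberately written in the most naive style possible
(explicit loops, full enumeration, textbook formulas) and shares no code
with the package.
"""

import itertools
import math

import numpy as np


def vec_lower(M):
    """Row-major lower triangle of a square array."""
    n = M.shape[0]
    return np.array([M[i, j] for i in range(1, n) for j in range(i)])


def pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))


def rank_avg(v):
    """Average ranks (1-based) with ties."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mantel_exhaustive(Dy, Dx, method="pearson"):
    """Exact one-sided upper-tail Mantel p over all n! relabelings."""
    n = Dy.shape[0]
    y = vec_lower(Dy)
    x = vec_lower(Dx)
    if method == "spearman":
        x = rank_avg(x)

    def stat(yv):
        yv = rank_avg(yv) if method == "spearman" else yv
        return pearson(yv, x)

    r_obs = stat(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        Dp = Dy[np.ix_(perm, perm)]
        if stat(vec_lower(Dp)) >= r_obs - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


def ols_standardized(y, X):
    """Normal-equations OLS on z-scored response and predictors."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    yz = (y - y.mean()) / y.std()
    Xz = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.linalg.inv(Xz.T @ Xz) @ (Xz.T @ yz)
    resid = yz - Xz @ beta
    r2 = 1 - (resid @ resid) / (yz @ yz)
    return beta, r2


def mrm_exhaustive(Dy, Dx_list, method="pearson"):
    """Exact two-sided per-coefficient MRM p over all n! relabelings."""
    n = Dy.shape[0]
    X = np.column_stack([vec_lower(D) for D in Dx_list])
    if method == "spearman":
        X = np.column_stack([rank_avg(X[:, j]) for j in range(X.shape[1])])

    def coefs(Dperm):
        yv = vec_lower(Dperm)
        if method == "spearman":
            yv = rank_avg(yv)
        beta, _ = ols_standardized(yv, X)
        return beta

    b_obs, r2 = None, None
    yv0 = vec_lower(Dy)
    if method == "spearman":
        yv0 = rank_avg(yv0)
    b_obs, r2 = ols_standardized(yv0, X)
    counts = np.zeros(len(Dx_list))
    total = 0
    for perm in itertools.permutations(range(n)):
        b = coefs(Dy[np.ix_(perm, perm)])
        counts += np.abs(b) >= np.abs(b_obs) - 1e-12
        total += 1
    return b_obs, r2, counts / total


def perm_ttest_exhaustive(a, b):
    """Exact two-sided permutation p for the difference of means."""
    a = list(a)
    b = list(b)
    pooled = a + b
    na = len(a)
    obs = np.mean(a) - np.mean(b)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(np.mean(ga) - np.mean(gb)) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return obs, count / total


def bh_stepup(p):
    """Textbook Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


# ---------------------------------------------------------------- trees
def tree_to_table(tree):
    """dendropy tree -> (children dict, branch length dict, root id)."""
    children = {}
    blen = {}
    for nd in tree.preorder_node_iter():
        nid = id(nd)
        children[nid] = [id(c) for c in nd.child_nodes()]
        blen[nid] = nd.edge.length if nd.edge.length is not None else 0.0
    tips = {id(leaf): leaf.taxon.label for leaf in tree.leaf_node_iter()}
    return children, blen, tips, id(tree.seed_node)


def pic_recursive(tree, tip_values):
    """Independently coded recursive contrast computation."""
    children, blen, tips, root = tree_to_table(tree)
    contrasts = []

    def visit(nid):
        # returns (value, effective branch length to parent)
        if not children[nid]:
            return float(tip_values[tips[nid]]), blen[nid]
        assert len(children[nid]) == 2, "oracle assumes binary trees"
        (x1, b1) = visit(children[nid][0])
        (x2, b2) = visit(children[nid][1])
        contrasts.append((x1 - x2) / math.sqrt(b1 + b2))
        val = (x1 / b1 + x2 / b2) / (1 / b1 + 1 / b2)
        return val, blen[nid] + b1 * b2 / (b1 + b2)

    visit(root)
    return np.array(contrasts)


def allpairs_tip_paths(tree):
    """All tip-to-tip path lengths via explicit root paths."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        p = []
        nd = leaf
        while nd is not None:
            p.append((id(nd), nd.edge.length or 0.0))
            nd = nd.parent_node
        paths[leaf.taxon.label] = p
    out = {}
    for a in paths:
        for b in paths:
            if a >= b:
                continue
            ids_a = {nid: i for i, (nid, _) in enumerate(paths[a])}
            for i, (nid, _) in enumerate(paths[b]):
                if nid in ids_a:
                    ia, ib = ids_a[nid], i
                    break
            d = sum(x for _, x in paths[a][:ia]) + sum(x for _, x in paths[b][:ib])
            out[(a, b)] = d
    return out
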