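"""Independent naive reference implementations used only by the tests.

Everything here is deliberately written by the most literal route available
(explicit loops, linear programming for hull membership, networkx for the
MST) so it shares no code path with the package implementations it checks.
"""

import numpy as np
import networkx as nx
from scipy.optimize import linprog


def naive_gower(values, kinds, ranges=None):
    """Pairwise Gower dissimilarity by explicit double loop.

    values: list of per-species trait tuples; kinds: 'q' or 'c' per trait.
    """
    n = len(values)
    p = len(kinds)
    if ranges is None:
        ranges = []
        for t in range(p):
            if kinds[t] == "q":
                col = [v[t] for v in values if v[t] is not None]
                ranges.append(max(col) - min(col))
            else:
                ranges.append(None)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num, cnt = 0.0, 0
            for t in range(p):
                a, b = values[i][t], values[j][t]
                if a is None or b is None:
                    continue
                if kinds[t] == "q":
                    if ranges[t] == 0:
                        continue
                    num += abs(a - b) / ranges[t]
                else:
                    num += 0.0 if a == b else 1.0
                cnt += 1
            d[i, j] = num / cnt if cnt else np.nan
    return d


def naive_fdis(x, w):
    x, w = np.asarray(x, float), np.asarray(w, float)
    keep = w > 0
    x, w = x[keep], w[keep] / w[keep].sum()
    c = sum(w[i] * x[i] for i in range(len(w)))
    return sum(w[i] * np.sqrt(((x[i] - c) ** 2).sum()) for i in range(len(w)))


def hull_vertices_lp(x):
    """Convex-hull vertex indices via LP feasibility (no Qhull).

    Point i is a vertex iff it cannot be written as a convex combination of
    the other points.
    """
    x = np.asarray(x, float)
    n = x.shape[0]
    verts = []
    for i in range(n):
        others = np.delete(x, i, axis=0)
        m = others.shape[0]
        # find mu >= 0, sum mu = 1, others^T mu = x_i
        A_eq = np.vstack([others.T, np.ones(m)])
        b_eq = np.concatenate([x[i], [1.0]])
        res = linprog(np.zeros(m), A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * m, method="highs")
        if not res.success:
            verts.append(i)
    return np.array(verts)


def naive_fdiv(x, w):
    x, w = np.asarray(x, float), np.asarray(w, float)
    keep = w > 0
    x, w = x[keep], w[keep] / w[keep].sum()
    if len(w) < 3:
        return float("nan")
    verts = hull_vertices_lp(x)
    g = x[verts].mean(axis=0)
    dG = np.array([np.sqrt(((xi - g) ** 2).sum()) for xi in x])
    mean_dG = dG.mean()
    delta_d = sum(w[i] * (dG[i] - mean_dG) for i in range(len(w)))
    delta_abs = sum(w[i] * abs(dG[i] - mean_dG) for i in range(len(w)))
    return (delta_d + mean_dG) / (delta_abs + mean_dG)


def naive_feve(x, w):
    x, w = np.asarray(x, float), np.asarray(w, float)
    keep = w > 0
    x, w = x[keep], w[keep] / w[keep].sum()
    s = len(w)
    if s < 3:
        return float("nan")
    g = nx.Graph()
    for i in range(s):
        for j in range(i + 1, s):
            g.add_edge(i, j, weight=float(np.sqrt(((x[i] - x[j]) ** 2).sum())))
    mst = nx.minimum_spanning_tree(g)
    ew = [mst[i][j]["weight"] / (w[i] + w[j]) for i, j in mst.edges]
    pew = np.array(ew) / np.sum(ew)
    thr = 1.0 / (s - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1 - thr)


def naive_uniqueness(d, w):
    d, w = np.asarray(d, float), np.asarray(w, float)
    keep = w > 0
    d = d[np.ix_(keep, keep)]
    w = w[keep] / w[keep].sum()
    s = len(w)
    q = sum(w[i] * w[j] * d[i, j] for i in range(s) for j in range(s))
    simpson = 1 - sum(wi**2 for wi in w)
    return q / simpson


def naive_mpd(d, w):
    d, w = np.asarray(d, float), np.asarray(w, float)
    keep = w > 0
    d = d[np.ix_(keep, keep)]
    w = w[keep] / w[keep].sum()
    s = len(w)
    num = den = 0.0
    for i in range(s):
        for j in range(s):
            if i != j:
                num += w[i] * w[j] * d[i, j]
                den += w[i] * w[j]
    return num / den


def naive_mntd(d, w):
    d, w = np.asarray(d, float), np.asarray(w, float)
    keep = w > 0
    d = d[np.ix_(keep, keep)]
    w = w[keep] / w[keep].sum()
    s = len(w)
    total = 0.0
    for i in range(s):
        nearest = min(d[i, j] for j in range(s) if j != i)
        total += w[i] * nearest
    return total


def naive_cophenetic(tree):
    """Patristic distances by walking parent chains to the common ancestor."""
    t = tree.tree
    leaves = list(t.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]

    def path_to_root(node):
        chain = []
        while node is not None:
            chain.append(node)
            node = node.parent_node
        return chain

    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        ci = path_to_root(leaves[i])
        for j in range(i + 1, n):
            cj = path_to_root(leaves[j])
            seti = set(id(x) for x in ci)
            mrca = next(x for x in cj if id(x) in seti)
            dist = 0.0
            for node in ci:
                if node is mrca:
                    break
                dist += node.edge.length
            for node in cj:
                if node is mrca:
                    break
                dist += node.edge.length
            d[i, j] = d[j, i] = dist
    return labels, d


def naive_spearman(x, y):
    """Spearman rho with mid-ranks, by the Pearson-of-ranks definition."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return np.array(ranks)

    rx, ry = midranks(list(x)), midranks(list(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
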