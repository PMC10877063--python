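"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (pair counting, path enumeration,
direct formula evaluation) and shares no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_midranks(v):
    """Mid-ranks (average rank for ties), 1-based, by direct scanning."""
    v = list(v)
    out = []
    for x in v:
        less = sum(1 for y in v if y < x)
        equal = sum(1 for y in v if y == x)
        out.append(less + (equal + 1) / 2.0)
    return np.array(out)


def bf_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def bf_spearman(x, y):
    """Pearson correlation of mid-ranks."""
    return bf_pearson(bf_midranks(x), bf_midranks(y))


def bf_kruskal(values, groups):
    """Kruskal-Wallis H with the tie correction, from the rank formula."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = bf_midranks(values)
    labels = sorted(set(groups.tolist()))
    h = 0.0
    for g in labels:
        r = ranks[groups == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    for val in set(values.tolist()):
        t = int((values == val).sum())
        ties += t**3 - t
    corr = 1.0 - ties / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def bf_holm(pvals):
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * p[i])
        running = max(running, val)
        adj[i] = running
    return np.array(adj)


def bf_ari(a, b):
    """Adjusted Rand index by O(n^2) pair counting."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        if sa and sb:
            n11 += 1
        elif sa and not sb:
            n10 += 1
        elif not sa and sb:
            n01 += 1
        else:
            n00 += 1
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return num / den if den else 1.0


def bf_modularity(edges, module_of):
    """Weighted Newman-Girvan Q from the pairwise definition.

    ``edges`` is an iterable of (u, v, w).
    """
    w_total = sum(w for _, _, w in edges)
    strength: dict = {}
    for u, v, w in edges:
        strength[u] = strength.get(u, 0.0) + w
        strength[v] = strength.get(v, 0.0) + w
    intra: dict = {}
    for u, v, w in edges:
        if module_of[u] == module_of[v]:
            intra[module_of[u]] = intra.get(module_of[u], 0.0) + w
    mod_strength: dict = {}
    for node, s in strength.items():
        c = module_of[node]
        mod_strength[c] = mod_strength.get(c, 0.0) + s
    q = 0.0
    for c in set(module_of.values()):
        q += intra.get(c, 0.0) / w_total - (
            mod_strength.get(c, 0.0) / (2.0 * w_total)
        ) ** 2
    return q


def bf_betweenness(nodes, edges):
    """Unweighted betweenness by enumerating all simple paths per pair.

    Exponential; only for graphs of ~a dozen nodes.
    """
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_paths(s, t):
        paths = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))
        return paths

    btw = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for p in sp:
            for inner in p[1:-1]:
                btw[inner] += 1.0 / len(sp)
    return btw


def bf_best_partition_q(nodes, edges):
    """Exhaustive best modularity over all set partitions (<= ~8 nodes)."""
    nodes = list(nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [first]] + part[i + 1:]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(nodes):
        module_of = {n: i for i, block in enumerate(part) for n in block}
        q = bf_modularity([(u, v, 1.0) for u, v in edges], module_of)
        best = max(best, q)
    return best
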