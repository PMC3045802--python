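"""Independent brute-force reference implementations used only by tests.

Everything here works by exhaustive enumeration (DFS over all simple
paths, pairwise vector comparison, 2^N sign patterns) so it stays
independent of the graph libraries and dynamic programming the package
itself uses.
"""

from __future__ import annotations

import itertools
from collections import defaultdict


def _successors(nodes, directed_edges):
    succ = defaultdict(set)
    for u, v in directed_edges:
        succ[u].add(v)
    return succ


def all_simple_paths(succ, s, t, max_len):
    """All simple s->t paths up to max_len edges, by DFS."""
    paths = []

    def dfs(path):
        node = path[-1]
        if node == t:
            paths.append(list(path))
            return
        if len(path) > max_len:
            return
        for nxt in succ[node]:
            if nxt not in path:
                path.append(nxt)
                dfs(path)
                path.pop()

    dfs([s])
    return paths


def shortest_paths(succ, s, t, n_nodes):
    """All shortest s->t paths (possibly none)."""
    paths = all_simple_paths(succ, s, t, n_nodes)
    if not paths:
        return []
    best = min(len(p) for p in paths)
    return [p for p in paths if len(p) == best]


def brute_betweenness(nodes, directed_edges, ordered_pairs: bool):
    """sigma_st(g)/sigma_st summed over source-target pairs, per node g.

    ``ordered_pairs`` selects ordered (directed-graph) versus unordered
    (pure-undirected) pair enumeration; for the unordered case
    ``directed_edges`` must contain both directions of every edge.
    """
    nodes = list(nodes)
    succ = _successors(nodes, directed_edges)
    values = {g: 0.0 for g in nodes}
    if ordered_pairs:
        pairs = [(s, t) for s in nodes for t in nodes if s != t]
    else:
        pairs = [(s, t) for i, s in enumerate(nodes) for t in nodes[i + 1:]]
    for s, t in pairs:
        paths = shortest_paths(succ, s, t, len(nodes))
        if not paths:
            continue
        for g in nodes:
            if g in (s, t):
                continue
            through = sum(1 for p in paths if g in p)
            values[g] += through / len(paths)
    return values


def brute_closeness(nodes, directed_edges, gene):
    """Mean shortest-path length from gene to each reachable node; 0 if none."""
    nodes = list(nodes)
    succ = _successors(nodes, directed_edges)
    lengths = []
    for t in nodes:
        if t == gene:
            continue
        paths = shortest_paths(succ, gene, t, len(nodes))
        if paths:
            lengths.append(len(paths[0]) - 1)
    return sum(lengths) / len(lengths) if lengths else 0.0


def brute_clustering(nodes, undirected_edges, gene):
    """Neighbor-pair link counting on an undirected edge set."""
    edges = {frozenset(e) for e in undirected_edges}
    neighbors = {v for e in edges if gene in e for v in e if v != gene}
    k = len(neighbors)
    if k < 2:
        return 0.0
    linked = sum(
        1 for a, b in itertools.combinations(sorted(neighbors), 2)
        if frozenset((a, b)) in edges
    )
    return linked / (k * (k - 1) / 2)


def brute_identicalness(vectors: dict, decimals: int = 9):
    """Pairwise comparison of rounded feature vectors; self included."""
    rounded = {
        g: tuple(round(float(x), decimals) for x in v) for g, v in vectors.items()
    }
    return {
        g: sum(1 for other in rounded.values() if other == rounded[g])
        for g in rounded
    }


def brute_wilcoxon(a, b):
    """Exhaustive 2^N sign-pattern Wilcoxon: (W, N, two-tailed p).

    Mid-ranks on tied absolute differences, zero differences discarded.
    Returns (None, 0, None) when all differences are zero.
    """
    d = [x - y for x, y in zip(a, b) if x != y]
    n = len(d)
    if n == 0:
        return None, 0, None
    abs_d = sorted((abs(x), i) for i, x in enumerate(d))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs_d[j + 1][0] == abs_d[i][0]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[abs_d[k][1]] = mid
        i = j + 1
    w_pos = sum(r for x, r in zip(d, ranks) if x > 0)
    w_neg = sum(r for x, r in zip(d, ranks) if x < 0)
    w = min(w_pos, w_neg)
    at_most = 0
    for signs in itertools.product((0, 1), repeat=n):
        s = sum(r for bit, r in zip(signs, ranks) if bit)
        if s <= w + 1e-9:
            at_most += 1
    p = min(1.0, 2 * at_most / 2**n)
    return w, n, p


def brute_auc(labels, scores):
    """Mann-Whitney pair counting with half credit for ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    u = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return u / (len(pos) * len(neg))


def brute_metabolic_edges(reactions, currency):
    """Double loop over reaction pairs: g1 -> g2 via a shared metabolite."""
    currency = set(currency)
    edges = set()
    for r1 in reactions:
        for r2 in reactions:
            shared = (set(r1.products) - currency) & set(r2.reactants)
            if not shared:
                continue
            for g1 in r1.genes:
                for g2 in r2.genes:
                    if g1 != g2:
                        edges.add((g1, g2))
    return edges
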