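"""Independent brute-force oracles used to verify the statistical routines.

Everything here is deliberately naive — enumeration of draws, enumeration
of rank assignments, exhaustive geodesic path listing, literal running
sums — and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def hypergeom_tails_exact(G: int, K: int, n: int, k: int) -> tuple[Fraction, Fraction]:
    """(P(X <= k), P(X >= k)) as exact rationals from the counting formula."""
    denom = comb(G, n)
    lower = sum(comb(K, j) * comb(G - K, n - j) for j in range(0, k + 1))
    upper = sum(comb(K, j) * comb(G - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(lower, denom), Fraction(upper, denom)


def hypergeom_tails_enumerated(G: int, K: int, n: int, k: int) -> tuple[Fraction, Fraction]:
    """Same tails by literally enumerating every size-n draw from the universe."""
    universe = range(G)
    marked = set(range(K))  # which elements are 'associated' is exchangeable
    le = ge = total = 0
    for draw in itertools.combinations(universe, n):
        overlap = len(marked.intersection(draw))
        total += 1
        le += overlap <= k
        ge += overlap >= k
    return Fraction(le, total), Fraction(ge, total)


def ranksum_exact_pvalues(a: list[float], b: list[float]) -> dict[str, Fraction]:
    """Exact Mann-Whitney p-values by enumerating all rank assignments.

    Requires tie-free pooled data. Returns one-sided ('less', 'greater')
    and two-sided (double the smaller tail, capped at 1) p-values.
    """
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    na, nb = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    positions = range(na + nb)
    le = ge = total = 0
    for a_pos in itertools.combinations(positions, na):
        a_set = set(a_pos)
        u = sum(1 for i in a_pos for j in positions if j not in a_set and i > j)
        total += 1
        le += u <= u_obs
        ge += u >= u_obs
    p_less = Fraction(le, total)
    p_greater = Fraction(ge, total)
    return {
        "less": p_less,
        "greater": p_greater,
        "two-sided": min(Fraction(1), 2 * min(p_less, p_greater)),
    }


def brute_force_degree_pct(nodes: list, edges: set) -> dict:
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    n = len(nodes)
    if n < 2:
        return {v: 0.0 for v in nodes}
    return {v: len(adj[v]) / (n - 1) * 100.0 for v in nodes}


def brute_force_betweenness_norm(nodes: list, edges: set) -> dict:
    """Normalized betweenness by exhaustively listing every geodesic."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_shortest_paths(s, t):
        dist = {s: 0}
        q = deque([s])
        while q:
            v = q.popleft()
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    q.append(w)
        if t not in dist:
            return []
        paths = []

        def extend(path):
            v = path[-1]
            if v == t:
                paths.append(list(path))
                return
            for w in adj[v]:
                if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                    path.append(w)
                    extend(path)
                    path.pop()

        extend([s])
        return paths

    score = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                score[v] += Fraction(1, len(paths))
    n = len(nodes)
    if n < 3:
        return {v: 0.0 for v in nodes}
    norm = Fraction((n - 1) * (n - 2), 2)
    return {v: float(score[v] / norm) for v in nodes}


def running_sum_es(ranked_genes, scores, members, weight_exponent=1.0) -> float:
    """Literal step-by-step running-sum enrichment score."""
    hits = [g in members for g in ranked_genes]
    n = len(ranked_genes)
    m = sum(hits)
    assert m > 0
    total = sum(abs(s) ** weight_exponent for s, h in zip(scores, hits) if h)
    running = 0.0
    hi = lo = 0.0
    for g, s, h in zip(ranked_genes, scores, hits):
        if h:
            running += (abs(s) ** weight_exponent / total) if total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        hi = max(hi, running)
        lo = min(lo, running)
    # on an exact |max| == |min| tie the positive deviation wins
    return hi if hi >= -lo else lo


def bh_stepup(p_values: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg step-up with cummin from the largest rank."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p_values[i] * m / (rank_idx + 1))
        q[i] = val
        prev = val
    return q
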