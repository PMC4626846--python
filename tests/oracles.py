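"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — BFS plus explicit shortest-path
backtracking for betweenness, exact integer arithmetic for the
hypergeometric tail — kept free of the library code paths they check.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb


def _bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(adj: dict, dist: dict, source, target) -> list[tuple]:
    """Every shortest source->target path, by backtracking from target."""
    if target not in dist:
        return []
    paths = []

    def back(node, suffix):
        if node == source:
            paths.append((source, *suffix))
            return
        for prev in adj[node]:
            if prev in dist and dist[prev] == dist[node] - 1:
                back(prev, (node, *suffix))

    back(target, ())
    return paths


def betweenness_oracle(nodes: list, edges: list[tuple]) -> dict:
    """Standardized betweenness by exhaustive shortest-path enumeration.

    BC_i = [sum over ordered pairs (j, k), j != i != k, of g_jk(i)/g_jk]
    / ((N-1)(N-2)). Unreachable pairs contribute 0. All scores 0 for
    N < 3.
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    n = len(nodes)
    scores = {v: Fraction(0) for v in nodes}
    if n < 3:
        return {v: 0.0 for v in nodes}
    for j in nodes:
        dist = _bfs_distances(adj, j)
        for k in nodes:
            if k == j or k not in dist:
                continue
            paths = _all_shortest_paths(adj, dist, j, k)
            g_jk = len(paths)
            for i in nodes:
                if i == j or i == k:
                    continue
                g_jk_i = sum(1 for p in paths if i in p)
                scores[i] += Fraction(g_jk_i, g_jk)
    denom = (n - 1) * (n - 2)
    return {v: float(s / denom) for v, s in scores.items()}


def hypergeom_pmf_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact hypergeometric p.m.f. by direct binomial-coefficient ratio."""
    return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))


def hypergeom_upper_oracle(N: int, K: int, n: int, x: int) -> float:
    """Exact strict upper tail P(X > x) by direct p.m.f. summation."""
    total = Fraction(0)
    for k in range(x + 1, min(K, n) + 1):
        total += hypergeom_pmf_exact(N, K, n, k)
    return float(total)


def hypergeom_lower_oracle(N: int, K: int, n: int, x: int) -> float:
    """Exact P(X <= x) by direct p.m.f. summation."""
    total = Fraction(0)
    for k in range(max(0, n - (N - K)), x + 1):
        total += hypergeom_pmf_exact(N, K, n, k)
    return float(total)
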