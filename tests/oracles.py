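"""Independent brute-force oracles used to verify the package.

Everything here is deliberately naive and self-contained (no networkx,
no scipy): exact integer hypergeometric tails, Floyd-Warshall distances,
exhaustive shortest-path enumeration, and subset-enumeration maximal
cliques. Only usable at toy sizes.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def exact_hypergeom_tail(N: int, M: int, n: int, k: int) -> Fraction:
    """P(X >= k) by direct integer PMF summation."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(M, n) + 1):
        if n - i > N - M:
            continue
        acc += math.comb(M, i) * math.comb(N - M, n - i)
    return Fraction(acc, total)


# --- tiny-graph helpers -----------------------------------------------------


def adjacency(vertices, edges):
    adj = {v: set() for v in vertices}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def floyd_warshall(vertices, edges):
    inf = math.inf
    dist = {u: {v: (0 if u == v else inf) for v in vertices} for u in vertices}
    for u, v in edges:
        dist[u][v] = dist[v][u] = 1
    for w in vertices:
        for u in vertices:
            for v in vertices:
                alt = dist[u][w] + dist[w][v]
                if alt < dist[u][v]:
                    dist[u][v] = alt
    return dist


def all_shortest_paths(adj, dist, s, t):
    """Every shortest s-t path, by DFS guided by exact distances."""
    if math.isinf(dist[s][t]):
        return []
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for w in adj[last]:
            if dist[s][w] == dist[s][last] + 1 and dist[w][t] == dist[last][t] - 1:
                path.append(w)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_degree(vertices, edges):
    counts = {v: 0 for v in vertices}
    for u, v in edges:
        counts[u] += 1
        counts[v] += 1
    return {v: float(c) for v, c in counts.items()}


def brute_closeness(vertices, edges):
    dist = floyd_warshall(vertices, edges)
    return {
        v: sum(
            1.0 / dist[v][w]
            for w in vertices
            if w != v and not math.isinf(dist[v][w])
        )
        for v in vertices
    }


def brute_betweenness_and_stress(vertices, edges):
    """Both path-census centralities from one exhaustive enumeration."""
    adj = adjacency(vertices, edges)
    dist = floyd_warshall(vertices, edges)
    betweenness = {v: 0.0 for v in vertices}
    stress = {v: 0.0 for v in vertices}
    for s, t in combinations(vertices, 2):
        paths = all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        sigma = len(paths)
        through = {v: 0 for v in vertices}
        for path in paths:
            for v in path[1:-1]:
                through[v] += 1
        for v in vertices:
            betweenness[v] += through[v] / sigma
            stress[v] += through[v]
    return betweenness, stress


def brute_maximal_cliques(vertices, edges):
    """All maximal cliques of size >= 2 by subset enumeration."""
    vertices = list(vertices)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(subset):
        return all(
            frozenset((a, b)) in edge_set for a, b in combinations(subset, 2)
        )

    cliques = []
    for r in range(2, len(vertices) + 1):
        for subset in combinations(vertices, r):
            if is_clique(subset):
                cliques.append(frozenset(subset))
    return [
        c
        for c in cliques
        if not any(c < other for other in cliques)
    ]


def brute_mcc(vertices, edges):
    scores = {v: 0.0 for v in vertices}
    for clique in brute_maximal_cliques(vertices, edges):
        for v in clique:
            scores[v] += math.factorial(len(clique) - 1)
    return scores
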