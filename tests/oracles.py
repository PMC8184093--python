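"""Independent brute-force oracles used to validate graph statistics.

Everything here is deliberately naive — plain BFS, full shortest-path
enumeration, exhaustive partition search — and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_degree_centrality(adj: dict) -> dict:
    n = len(adj)
    return {u: len(adj[u]) / (n - 1) for u in adj}


def brute_closeness_centrality(adj: dict) -> dict:
    """Wasserman–Faust closeness; equals (n-1)/sum(d) when connected."""
    n = len(adj)
    out = {}
    for u in adj:
        dist = bfs_distances(adj, u)
        total = sum(d for v, d in dist.items() if v != u)
        reachable = len(dist) - 1
        if total == 0:
            out[u] = 0.0
        else:
            out[u] = (reachable / (n - 1)) * (reachable / total)
    return out


def _all_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """Every shortest s→t path, by BFS layering + DFS enumeration."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                extend(path + [v])

    extend([s])
    return paths


def brute_betweenness_centrality(adj: dict) -> dict:
    n = len(adj)
    score = {u: 0.0 for u in adj}
    for s, t in combinations(adj, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in adj:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = 2.0 / ((n - 1) * (n - 2))
    return {u: x * norm for u, x in score.items()}


def brute_best_bipartition(adj: dict, weights: dict) -> tuple[float, frozenset]:
    """Exhaustive max-modularity split into at most two groups.

    ``weights[(u, v)]`` is the symmetric edge weight. Returns the best
    modularity and one side of the best split.
    """
    nodes = sorted(adj)
    m = sum(weights.values())
    strength = {u: 0.0 for u in nodes}
    for (u, v), w in weights.items():
        strength[u] += w
        strength[v] += w

    def q(groups) -> float:
        total = 0.0
        for group in groups:
            internal = sum(w for (u, v), w in weights.items()
                           if u in group and v in group)
            deg = sum(strength[u] for u in group)
            total += internal / m - (deg / (2 * m)) ** 2
        return total

    best_q, best_side = q([set(nodes)]), frozenset(nodes)
    anchor = nodes[0]  # fix one node to halve the search space
    rest = nodes[1:]
    for r in range(len(rest) + 1):
        for side in combinations(rest, r):
            a = set(side) | {anchor}
            b = set(nodes) - a
            if not b:
                continue
            val = q([a, b])
            if val > best_q:
                best_q, best_side = val, frozenset(a)
    return best_q, best_side
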