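"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: betweenness by explicit
all-pairs BFS path counting, path enumeration by plain recursion, Mann-
Whitney by exhaustive arrangement enumeration, hypergeometric moments via
scipy's distribution object.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb

import numpy as np


def bfs_distances_and_counts(adj: dict[int, list[int]], source: int, n: int):
    """Unit-weight distances and shortest-path counts from one source."""
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[source] = 0
    sigma[source] = 1
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if np.isinf(dist[v]):
                dist[v] = dist[u] + 1
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def brute_force_betweenness(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Pair-normalized betweenness by explicit path counting (undirected)."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    D = np.empty((n, n))
    S = np.empty((n, n))
    for s in range(n):
        D[s], S[s] = bfs_distances_and_counts(adj, s, n)

    bet = np.zeros(n)
    pairs = np.triu(np.ones((n, n), dtype=bool), k=1)
    for v in range(n):
        through = D[:, v][:, None] + D[v, :][None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            on_path = np.isfinite(D) & (through == D)
            contrib = np.where(on_path, S[:, v][:, None] * S[v, :][None, :] / S, 0.0)
        contrib[v, :] = 0.0
        contrib[:, v] = 0.0
        bet[v] = contrib[pairs].sum()
    if n > 2:
        bet /= (n - 1) * (n - 2) / 2
    return bet


def recursive_simple_paths(
    adj: dict[str, list[str]], source: str, target: str, max_length: int
) -> list[list[str]]:
    """All simple paths of length <= max_length, by plain recursion."""
    out: list[list[str]] = []

    def walk(node: str, path: list[str]) -> None:
        if node == target:
            out.append(path.copy())
            return
        if len(path) > max_length:
            return
        for nxt in adj.get(node, []):
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    walk(source, [source])
    return [p for p in out if len(p) - 1 >= 1]


def bfs_all_shortest_paths(
    adj: dict[str, list[str]], source: str, target: str
) -> list[list[str]]:
    """All shortest paths via BFS layering plus backtracking."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, []):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if target not in dist:
        return []

    paths: list[list[str]] = []

    def back(path: list[str]) -> None:
        node = path[-1]
        if node == target:
            paths.append(path.copy())
            return
        for v in adj.get(node, []):
            if dist.get(v) == dist[path[-1]] + 1 and dist[v] <= dist[target]:
                path.append(v)
                back(path)
                path.pop()

    back([source])
    return sorted(p for p in paths if len(p) - 1 == dist[target])


def mann_whitney_enumeration(x, y, alternative: str = "greater") -> float:
    """Exact one/two-sided p by enumerating all group-label arrangements."""

    def u_stat(xs, ys) -> float:
        u = 0.0
        for xi in xs:
            for yi in ys:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    pooled = list(x) + list(y)
    n1 = len(x)
    observed = u_stat(x, y)
    count = 0
    total = 0
    idx = range(len(pooled))
    for combo in itertools.combinations(idx, n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if alternative == "greater":
            count += u >= observed
        elif alternative == "less":
            count += u <= observed
        else:
            full = len(x) * len(y)
            count += abs(u - full / 2) >= abs(observed - full / 2)
    return count / total


def hypergeom_tail_sum(N: int, R: int, n: int, r: int) -> float:
    """Exact upper-tail P(X >= r) via binomial coefficients."""
    return sum(comb(R, k) * comb(N - R, n - k) for k in range(r, min(n, R) + 1)) / comb(N, n)


def random_undirected_graph(rng: np.random.Generator, n: int, m: int):
    """m distinct edges over n labelled nodes."""
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    take = rng.choice(len(possible), size=min(m, len(possible)), replace=False)
    return [possible[int(i)] for i in take]


def random_directed_graph(rng: np.random.Generator, n: int, m: int):
    possible = [(i, j) for i in range(n) for j in range(n) if i != j]
    take = rng.choice(len(possible), size=min(m, len(possible)), replace=False)
    return [possible[int(i)] for i in take]
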