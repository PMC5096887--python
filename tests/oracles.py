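"""Independent brute-force graph-measure oracles for the test suite.

Everything here is computed from first principles (queue BFS, pair
enumeration, itertools triangle counting, exhaustive set partitions) and
deliberately shares no code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in np.flatnonzero(adj[u]):
                if np.isinf(dist[s, v]):
                    dist[s, v] = dist[s, u] + 1
                    q.append(v)
    return dist


def char_path_length(adj: np.ndarray) -> float:
    d = bfs_distances(adj)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def global_efficiency(adj: np.ndarray) -> float:
    d = bfs_distances(adj)
    n = d.shape[0]
    if n < 2:
        return 0.0
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0 for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def nodal_clustering(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def transitivity(adj: np.ndarray) -> float:
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    triangles = sum(
        1
        for a, b, c in itertools.combinations(range(n), 3)
        if adj[a, b] and adj[b, c] and adj[a, c]
    )
    triples = sum(int(adj[i].sum()) * (int(adj[i].sum()) - 1) // 2 for i in range(n))
    return 3.0 * triangles / triples if triples else 0.0


def local_efficiency(adj: np.ndarray) -> float:
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) >= 2:
            total += global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n if n else 0.0


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Path-count betweenness via shortest-path DP (not Brandes)."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    d = bfs_distances(adj)
    # sigma[s, t]: number of shortest s-t paths, by dynamic programming
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for t in sorted(range(n), key=lambda t: d[s, t]):
            if t == s or np.isinf(d[s, t]):
                continue
            sigma[s, t] = sum(
                sigma[s, u] for u in np.flatnonzero(adj[t]) if d[s, u] == d[s, t] - 1
            )
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if np.isinf(d[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t) or np.isinf(d[s, v]) or np.isinf(d[v, t]):
                continue
            if d[s, v] + d[v, t] == d[s, t]:
                bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def modularity_q(adj: np.ndarray, labels) -> float:
    adj = np.asarray(adj, dtype=float)
    labels = np.asarray(labels)
    two_e = adj.sum()
    k = adj.sum(axis=1)
    q = 0.0
    for m in set(labels.tolist()):
        idx = labels == m
        q += adj[np.ix_(idx, idx)].sum() / two_e - (k[idx].sum() / two_e) ** 2
    return float(q)


def _set_partitions(items: list[int]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_modularity(adj: np.ndarray) -> float:
    """Exhaustive maximum of Q over all partitions (feasible for n <= 8)."""
    n = adj.shape[0]
    best = -np.inf
    labels = np.empty(n, dtype=int)
    for part in _set_partitions(list(range(n))):
        for m, block in enumerate(part):
            labels[block] = m
        best = max(best, modularity_q(adj, labels))
    return float(best)


def largest_component(adj: np.ndarray) -> int:
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    seen = set()
    best = 0
    for s in range(n):
        if s in seen:
            continue
        comp = {s}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in np.flatnonzero(adj[u]):
                if v not in comp:
                    comp.add(int(v))
                    q.append(int(v))
        seen |= comp
        best = max(best, len(comp))
    return best


def random_graph(rng: np.random.Generator, n: int, p: float | None = None) -> np.ndarray:
    p = rng.uniform(0.2, 0.8) if p is None else p
    adj = rng.random((n, n)) < p
    adj = np.triu(adj, 1)
    return adj | adj.T
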