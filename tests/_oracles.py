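"""Independent brute-force oracles for graph metrics.

Everything here is deliberately naive — explicit BFS, explicit formula
evaluation, exhaustive search over set partitions — and shares no code
with the package implementation it checks.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by explicit BFS; inf if unreachable."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0.0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u, v] and np.isinf(D[s, v]):
                    D[s, v] = D[s, u] + 1
                    q.append(v)
    return D


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    D = bfs_distances(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def brute_local_efficiency(adj: np.ndarray) -> tuple[np.ndarray, float]:
    n = adj.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        eff[i] = brute_global_efficiency(sub)
    return eff, float(eff.mean()) if n else 0.0


def brute_participation(adj: np.ndarray, membership: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    pc = np.zeros(n)
    for i in range(n):
        k = int(adj[i].sum())
        if k == 0:
            continue
        acc = 0.0
        for s in np.unique(membership):
            k_is = int(adj[i, membership == s].sum())
            acc += (k_is / k) ** 2
        pc[i] = 1.0 - acc
    return pc


def newman_modularity(adj: np.ndarray, membership: np.ndarray, resolution: float = 1.0) -> float:
    """Newman-Girvan modularity with resolution, computed from scratch."""
    m2 = adj.sum()  # 2 * number of edges
    if m2 == 0:
        return 0.0
    deg = adj.sum(axis=1)
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += adj[i, j] - resolution * deg[i] * deg[j] / m2
    return q / m2


def _set_partitions(items):
    """Yield all set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def best_partition_exhaustive(adj: np.ndarray, resolution: float = 1.0):
    """Globally modularity-optimal partition by exhaustive search (n <= 8)."""
    n = adj.shape[0]
    assert n <= 8, "exhaustive search is for tiny graphs only"
    best_q, best_m = -np.inf, None
    for part in _set_partitions(list(range(n))):
        membership = np.empty(n, dtype=int)
        for cid, block in enumerate(part):
            for v in block:
                membership[v] = cid
        q = newman_modularity(adj, membership, resolution)
        if q > best_q + 1e-15:
            best_q, best_m = q, membership
    return best_m, best_q


def random_graph(rng: np.random.Generator, n_max: int = 8) -> np.ndarray:
    """A random simple undirected graph with 2..n_max nodes."""
    n = int(rng.integers(2, n_max + 1))
    p = rng.uniform(0.1, 0.9)
    A = (rng.random((n, n)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T
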