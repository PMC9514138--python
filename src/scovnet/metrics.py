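"""Graph metrics for binary undirected networks.

Three network parameters summarize integration and segregation:

* **Global efficiency** — the mean over node pairs of the inverse shortest
  path length (disconnected pairs contribute 0); an integration measure.
* **Mean local efficiency** — per node, the global efficiency of the
  subgraph induced by its neighbors (nodes of degree < 2 score 0),
  averaged over all nodes; a segregation measure.
* **Modularity, quantified as the mean participation coefficient** over a
  Louvain community partition: PC_i = 1 - sum_s (k_is / k_i)^2, where
  k_is counts node i's edges into module s.  A node whose edges stay in
  one module has PC 0.  Interpretation contract: HIGHER mean participation
  means edges spread across modules, i.e. LESS segregation between
  modules; lower mean participation means MORE segregated networks.

Shortest-path computations use scipy's compiled BFS; community detection
uses igraph's multilevel (Louvain) implementation, seeded and restarted.
Newman-Girvan modularity Q of the partition is carried as a diagnostic
only.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
from numba import njit


@dataclass
class CommunityPartition:
    """Node -> module assignment at a stated Louvain resolution."""

    membership: np.ndarray  # module id per node, contiguous from 0
    resolution: float
    quality: float  # Newman-Girvan modularity Q of the partition

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=np.int64)
        ids = np.unique(self.membership)
        if self.membership.size and not np.array_equal(ids, np.arange(ids.size)):
            raise ValueError("module ids must be contiguous from 0")

    @property
    def n_modules(self) -> int:
        return int(self.membership.max()) + 1 if self.membership.size else 0


@dataclass
class NetworkMetrics:
    """The three network parameters plus the partition they used."""

    local_efficiency_per_node: np.ndarray
    mean_local_efficiency: float
    global_efficiency: float
    participation_per_node: np.ndarray
    mean_participation: float
    partition: CommunityPartition


def _check_adjacency(A) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not (A == A.T).all() or A.diagonal().any() or not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency must be binary, symmetric, zero-diagonal")
    return A.astype(np.int8)


@njit(cache=True)
def _inv_distance_sum(A: np.ndarray) -> float:
    """Sum over ordered pairs of 1/d(i,j) by BFS; disconnected pairs add 0."""
    n = A.shape[0]
    total = 0.0
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    for s in range(n):
        for v in range(n):
            dist[v] = -1
        dist[s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for v in range(n):
                if A[u, v] != 0 and dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for t in range(n):
            if t != s and dist[t] > 0:
                total += 1.0 / dist[t]
    return total


@njit(cache=True)
def _local_efficiency_per_node(A: np.ndarray) -> np.ndarray:
    """Per node, the pairwise-inverse-distance mean of its neighborhood
    subgraph (degree < 2 scores 0)."""
    n = A.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        deg = 0
        for v in range(n):
            if A[i, v] != 0:
                deg += 1
        if deg < 2:
            continue
        nb = np.empty(deg, np.int64)
        c = 0
        for v in range(n):
            if A[i, v] != 0:
                nb[c] = v
                c += 1
        sub = np.empty((deg, deg), A.dtype)
        for a in range(deg):
            for b in range(deg):
                sub[a, b] = A[nb[a], nb[b]]
        eff[i] = _inv_distance_sum(sub) / (deg * (deg - 1))
    return eff


def _pairwise_inverse_distance_sum(A: np.ndarray) -> float:
    n = A.shape[0]
    if n < 2 or not A.any():
        return 0.0
    return float(_inv_distance_sum(np.ascontiguousarray(A)))


def global_efficiency(adjacency) -> float:
    """Mean inverse shortest-path length over all node pairs, in [0, 1]."""
    A = _check_adjacency(adjacency)
    n = A.shape[0]
    if n < 2:
        return 0.0
    return _pairwise_inverse_distance_sum(A) / (n * (n - 1))


def local_efficiency(adjacency) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its network mean.

    Node i's local efficiency is the global efficiency of the subgraph
    induced by i's neighbors (i itself excluded); degree < 2 scores 0.
    """
    A = _check_adjacency(adjacency)
    n = A.shape[0]
    if n == 0:
        return np.zeros(0), 0.0
    eff = _local_efficiency_per_node(np.ascontiguousarray(A))
    return eff, float(eff.mean())


def detect_communities(
    adjacency, resolution: float = 1.0, seed: int = 0, n_restarts: int = 5
) -> CommunityPartition:
    """Louvain modularity maximization at resolution gamma, seeded.

    Louvain is greedy and its output depends on the node visiting order,
    so the search runs ``n_restarts`` times with distinct sub-seeds and
    keeps the partition with the highest modularity at the requested
    resolution (the usual restart strategy).  Module ids are relabeled
    contiguously in order of each module's smallest node index, so the
    partition is a pure function of (adjacency, resolution, seed,
    n_restarts).  Isolated nodes end up as singleton modules.  An
    edgeless graph yields the all-singleton partition with quality 0 and
    a warning.
    """
    A = _check_adjacency(adjacency)
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    n = A.shape[0]
    if n == 0:
        return CommunityPartition(np.empty(0, dtype=np.int64), resolution, 0.0)
    if not A.any():
        warnings.warn("edgeless graph: returning all-singleton partition", stacklevel=2)
        return CommunityPartition(np.arange(n, dtype=np.int64), resolution, 0.0)
    edges = [(int(i), int(j)) for i, j in np.argwhere(np.triu(A, 1))]
    G = igraph.Graph(n=n, edges=edges)
    best_m, best_q = None, -np.inf
    for r in range(max(1, n_restarts)):
        igraph.set_random_number_generator(random.Random((int(seed) * 1009 + r) % (2**63)))
        part = G.community_multilevel(resolution=float(resolution))
        q_gamma = G.modularity(part.membership, resolution=float(resolution))
        if q_gamma > best_q:
            best_m, best_q = np.asarray(part.membership), q_gamma
    # relabel contiguously by smallest member node
    order = sorted(set(best_m), key=lambda c: int(np.flatnonzero(best_m == c)[0]))
    relabel = {c: i for i, c in enumerate(order)}
    membership = np.array([relabel[c] for c in best_m], dtype=np.int64)
    Q = float(G.modularity(membership.tolist()))
    return CommunityPartition(membership, float(resolution), Q)


def participation_coefficient(
    adjacency, partition: CommunityPartition
) -> tuple[np.ndarray, float]:
    """Per-node participation coefficients and their all-node mean.

    PC_i = 1 - sum_s (k_is / k_i)^2; degree-0 nodes score 0.  Values lie
    in [0, 1 - 1/n_modules].
    """
    A = _check_adjacency(adjacency)
    n = A.shape[0]
    if partition.membership.shape != (n,):
        raise ValueError(
            f"partition covers {partition.membership.size} nodes, adjacency has {n}"
        )
    k = A.sum(axis=1).astype(float)
    n_mod = partition.n_modules
    onehot = np.zeros((n, n_mod))
    onehot[np.arange(n), partition.membership] = 1.0
    k_is = A @ onehot  # (n, n_modules): edges from i into each module
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = k_is / k[:, None]
    pc = 1.0 - np.nansum(frac**2, axis=1)
    pc[k == 0] = 0.0
    return pc, float(pc.mean()) if n else 0.0


def compute_network_metrics(
    network_or_adjacency, resolution: float = 1.0, seed: int = 0
) -> NetworkMetrics:
    """Bundle the three network parameters for one network.

    Accepts a :class:`~scovnet.network.SparseNetwork` or a bare binary
    adjacency.  Identical adjacency, resolution and seed give identical
    metrics.
    """
    A = getattr(network_or_adjacency, "adjacency", network_or_adjacency)
    A = _check_adjacency(A)
    part = detect_communities(A, resolution=resolution, seed=seed)
    le, mle = local_efficiency(A)
    ge = global_efficiency(A)
    pc, mpc = participation_coefficient(A, part)
    return NetworkMetrics(
        local_efficiency_per_node=le,
        mean_local_efficiency=mle,
        global_efficiency=ge,
        participation_per_node=pc,
        mean_participation=mpc,
        partition=part,
    )


#: metric_name -> callable(adjacency, resolution, seed) -> float
def network_metric(
    adjacency, metric_name: str, resolution: float = 1.0, seed: int = 0,
    validate: bool = True,
) -> float:
    """Compute a single named network-level metric (cheaper than the bundle).

    ``validate=False`` skips the adjacency contract check; permutation loops
    use it on adjacencies they constructed themselves.
    """
    A = _check_adjacency(adjacency) if validate else adjacency
    n = A.shape[0]
    if metric_name == "global_efficiency":
        if n < 2 or not A.any():
            return 0.0
        return _inv_distance_sum(np.ascontiguousarray(A)) / (n * (n - 1))
    if metric_name == "local_efficiency":
        if n == 0:
            return 0.0
        return float(_local_efficiency_per_node(np.ascontiguousarray(A)).mean())
    if metric_name == "participation":
        if not A.any():
            return 0.0
        part = detect_communities(A, resolution=resolution, seed=seed)
        return participation_coefficient(A, part)[1]
    raise ValueError(
        f"unknown metric {metric_name!r}; expected one of "
        "'local_efficiency', 'global_efficiency', 'participation'"
    )


METRIC_NAMES = ("local_efficiency", "global_efficiency", "participation")
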