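"""Graph-theoretic measures of binary undirected networks.

Integration (characteristic path length, global efficiency), segregation
(clustering coefficient, local efficiency, transitivity, modularity), nodal
measures (degree, clustering, betweenness), degree-preserving random
reference networks, and the small-world index sigma = gamma / lambda where
gamma and lambda normalize clustering and path length by the mean over
rewired references.

Path-based measures are defined over reachable pairs: on a fragmented
network the characteristic path length averages finite distances only (and
the caller is warned), while global efficiency treats disconnected pairs as
zero efficiency.  The primary pipeline avoids fragmentation by working at or
above the minimum density, so these conventions only matter off-grid.

Shortest paths use a dense level-synchronous BFS, clustering, transitivity
and efficiency are direct linear algebra, and betweenness / greedy
modularity run through igraph's C implementations — together this keeps the
permutation loop fast at parcellation scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .network import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "GLOBAL_METRIC_NAMES",
    "char_path_length",
    "global_efficiency",
    "clustering_and_transitivity",
    "local_efficiency",
    "betweenness",
    "degrees",
    "modularity",
    "random_reference",
    "small_world",
    "global_metrics",
    "nodal_metrics",
]

#: Global measures comparable between groups (Table-1 set).
GLOBAL_METRIC_NAMES = (
    "char_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "local_efficiency",
    "transitivity",
    "modularity",
    "gamma",
    "lambda",
    "sigma",
)


class SmallWorld(NamedTuple):
    gamma: float
    lam: float
    sigma: float


@dataclass(frozen=True)
class GlobalMetrics:
    """All global measures of one network (small-world terms optional)."""

    char_path_length: float
    global_efficiency: float
    clustering_coefficient: float
    local_efficiency: float
    transitivity: float
    modularity: float
    gamma: float = np.nan
    lam: float = np.nan
    sigma: float = np.nan

    def as_dict(self) -> dict[str, float]:
        d = {
            "char_path_length": self.char_path_length,
            "global_efficiency": self.global_efficiency,
            "clustering_coefficient": self.clustering_coefficient,
            "local_efficiency": self.local_efficiency,
            "transitivity": self.transitivity,
            "modularity": self.modularity,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
        }
        return d


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net, dtype=bool)


def _igraph(adj: np.ndarray) -> ig.Graph:
    rows, cols = np.nonzero(np.triu(adj, 1))
    return ig.Graph(n=adj.shape[0], edges=list(zip(rows.tolist(), cols.tolist())))


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by dense level-synchronous BFS.

    One uint8 matrix product per BFS level; unreachable pairs are inf.  For
    the network sizes this package works at (tens to a few hundred nodes)
    this beats sparse-graph routines because it avoids per-call sparse
    construction overhead.
    """
    a = np.asarray(adj, dtype=np.uint8)
    n = a.shape[0]
    dist = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = dist < np.inf
    frontier = a > 0
    level = 1
    while frontier.any():
        nxt = (frontier.astype(np.uint8) @ a > 0) & ~reached
        if not nxt.any():
            break
        level += 1
        dist[nxt] = level
        reached |= nxt
        frontier = nxt
    return dist


# -- integration ------------------------------------------------------------


def char_path_length(net: BinaryNetwork | np.ndarray, *, warn_disconnected: bool = True) -> float:
    """Mean shortest-path length over reachable node pairs.

    On a connected graph this is the usual characteristic path length Lp; on
    a fragmented graph unreachable pairs are excluded and a warning flags the
    result.  An edgeless graph has no path and returns NaN (flagged).
    """
    adj = _adj(net)
    n = adj.shape[0]
    if n < 2 or not adj.any():
        warnings.warn("path length undefined on an edgeless graph", stacklevel=2)
        return float("nan")
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if warn_disconnected and finite.sum() < off.sum():
        warnings.warn(
            "graph is disconnected; path length averaged over reachable pairs only",
            stacklevel=2,
        )
    return float(d[finite].mean())


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length over all pairs (1/inf = 0)."""
    adj = _adj(net)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _distances(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


# -- segregation ------------------------------------------------------------


class ClusteringResult(NamedTuple):
    mean_clustering: float
    transitivity: float
    nodal: np.ndarray


def clustering_and_transitivity(net: BinaryNetwork | np.ndarray) -> ClusteringResult:
    """Nodal/mean clustering and whole-network transitivity.

    Nodal clustering is 2·(triangles at node) / k(k−1), zero for degree < 2;
    transitivity is 3·triangles / connected triples — the segregation measure
    insensitive to low-degree nodes.
    """
    a = _adj(net).astype(np.float64)
    k = a.sum(axis=1)
    a2 = a @ a
    # (A²∘A) row-sum i = 2 × triangles through node i
    tri2 = (a2 * a).sum(axis=1)
    denom = k * (k - 1)
    nodal = np.where(denom > 0, tri2 / np.where(denom > 0, denom, 1.0), 0.0)
    triples = denom.sum()
    transitivity = float(tri2.sum() / triples) if triples > 0 else 0.0
    return ClusteringResult(float(nodal.mean()) if nodal.size else 0.0, transitivity, nodal)


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph.

    The node itself is excluded from its neighborhood; nodes with fewer than
    two neighbors contribute zero.
    """
    adj = _adj(net)
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        total += global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n if n else 0.0


def modularity(net: BinaryNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Newman modularity Q of a deterministic greedy agglomerative partition.

    Q = Σ_m (e_m/E − (d_m/2E)²).  The partition comes from greedy
    agglomeration (Clauset–Newman–Moore), which is deterministic for a fixed
    node order; its optimality gap on small graphs is bounded in the test
    suite against exhaustive partition search.  Returns (Q, module label per
    node).  Raises on an edgeless graph (Q undefined).
    """
    adj = _adj(net)
    if not adj.any():
        raise ValueError("modularity undefined on an edgeless graph")
    g = _igraph(adj)
    membership = np.asarray(
        g.community_fastgreedy().as_clustering().membership, dtype=int
    )
    # stable module numbering: order modules by their smallest node index
    order = {m: i for i, m in enumerate(sorted(set(membership), key=lambda m: int(np.argmax(membership == m))))}
    labels = np.array([order[m] for m in membership], dtype=int)
    q = float(g.modularity(labels.tolist()))
    return q, labels


def modularity_q(partition_labels: np.ndarray, adj: np.ndarray) -> float:
    """Q of a given partition (used by oracles and module-recovery tests)."""
    a = np.asarray(adj, dtype=float)
    e2 = a.sum()  # 2E
    if e2 == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    k = a.sum(axis=1)
    q = 0.0
    for m in np.unique(partition_labels):
        idx = partition_labels == m
        q += a[np.ix_(idx, idx)].sum() / e2 - (k[idx].sum() / e2) ** 2
    return float(q)


# -- nodal ------------------------------------------------------------------


def degrees(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    return _adj(net).sum(axis=1).astype(int)


def betweenness(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized shortest-path betweenness per node.

    Each unordered pair contributes once, with credit split equally among
    equal-length shortest paths (Brandes accumulation).
    """
    adj = _adj(net)
    return np.asarray(_igraph(adj).betweenness(), dtype=float)


def nodal_metrics(net: BinaryNetwork) -> pd.DataFrame:
    """Degree, clustering and betweenness per region (region order preserved)."""
    clus = clustering_and_transitivity(net).nodal
    return pd.DataFrame(
        {
            "degree": degrees(net),
            "clustering": clus,
            "betweenness": betweenness(net),
        },
        index=list(net.labels),
    )


# -- random references and small-worldness ----------------------------------


def _swap_once(adj: np.ndarray, edges: list[list[int]], e1: int, e2: int, flip: bool) -> bool:
    a, b = edges[e1]
    c, d = edges[e2]
    if flip:
        c, d = d, c
    if len({a, b, c, d}) < 4 or adj[a, d] or adj[c, b]:
        return False
    adj[a, b] = adj[b, a] = False
    adj[c, d] = adj[d, c] = False
    adj[a, d] = adj[d, a] = True
    adj[c, b] = adj[b, c] = True
    edges[e1] = [a, d]
    edges[e2] = [c, b]
    return True


def _rewire(adj: np.ndarray, rng: np.random.Generator, swap_factor: int) -> np.ndarray:
    """Maslov–Sneppen double-edge swap: ``swap_factor × E`` attempted swaps."""
    out = adj.copy()
    edges = np.argwhere(np.triu(out, 1)).tolist()
    e = len(edges)
    n_attempts = swap_factor * e
    idx = rng.integers(0, e, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (e1, e2), flip in zip(idx, flips):
        if e1 != e2:
            _swap_once(out, edges, int(e1), int(e2), bool(flip))
    return out


def random_reference(
    net: BinaryNetwork,
    seed: int | np.random.Generator | None = None,
    n_networks: int = 20,
    *,
    swap_factor: int = 100,
    require_connected: bool | None = None,
    max_redraws: int = 20,
) -> list[BinaryNetwork]:
    """Degree-preserving rewired null networks.

    Each reference is produced by ``swap_factor × E`` attempted double-edge
    swaps, preserving the exact degree sequence.  When the input is connected
    (or ``require_connected=True``), disconnected rewires are discarded and
    redrawn up to ``max_redraws`` times each; for a fragmented input any
    degree-preserving rewire is accepted.  Seeded and bit-reproducible.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    adj = net.adjacency
    if net.n_edges < 2:
        raise ValueError("graph too small to rewire (needs >= 2 edges)")
    if require_connected is None:
        require_connected = net.is_connected
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    refs: list[BinaryNetwork] = []
    for _ in range(n_networks):
        for attempt in range(max_redraws + 1):
            rewired = _rewire(adj, rng, swap_factor)
            candidate = BinaryNetwork(
                adjacency=rewired, density=net.density, group=f"{net.group}:rewired", labels=net.labels
            )
            if not require_connected or candidate.is_connected:
                refs.append(candidate)
                break
        else:
            raise RuntimeError(
                f"could not draw a connected rewired reference in {max_redraws + 1} tries"
            )
    return refs


def small_world(net: BinaryNetwork | np.ndarray, refs: Sequence[BinaryNetwork | np.ndarray]) -> SmallWorld:
    """gamma = Cp/⟨Cp_rand⟩, lambda = Lp/⟨Lp_rand⟩, sigma = gamma/lambda.

    Ratio-of-means normalization: the reference clustering and path length
    are each averaged over the rewired networks before dividing.  sigma > 1
    is the small-world signature (clustering well above random at a similar
    path length).
    """
    if not refs:
        raise ValueError("at least one reference network is required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cp = clustering_and_transitivity(net).mean_clustering
        lp = char_path_length(net, warn_disconnected=False)
        cp_r = float(np.mean([clustering_and_transitivity(r).mean_clustering for r in refs]))
        lp_r = float(np.mean([char_path_length(r, warn_disconnected=False) for r in refs]))
    gamma = cp / cp_r if cp_r > 0 else float("nan")
    lam = lp / lp_r if lp_r > 0 else float("nan")
    sigma = gamma / lam if lam and np.isfinite(lam) else float("nan")
    return SmallWorld(gamma=float(gamma), lam=float(lam), sigma=float(sigma))


def global_metrics(
    net: BinaryNetwork,
    refs: Iterable[BinaryNetwork] | None = None,
) -> GlobalMetrics:
    """All global measures of one network; small-world terms need ``refs``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clus = clustering_and_transitivity(net)
        q, _ = modularity(net) if net.n_edges else (float("nan"), None)
        sw = small_world(net, list(refs)) if refs else SmallWorld(np.nan, np.nan, np.nan)
        return GlobalMetrics(
            char_path_length=char_path_length(net, warn_disconnected=False),
            global_efficiency=global_efficiency(net),
            clustering_coefficient=clus.mean_clustering,
            local_efficiency=local_efficiency(net),
            transitivity=clus.transitivity,
            modularity=q,
            gamma=sw.gamma,
            lam=sw.lam,
            sigma=sw.sigma,
        )
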