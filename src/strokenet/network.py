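"""Binary brain graphs at fixed sparsity and their topological metrics.

A sparsity threshold keeps the k = round(s * N(N-1)/2) strongest wPLI
edges, so every subject's graph has the same edge count and metric
differences reflect topology, not overall connectivity strength.

Metrics follow the standard binary-graph definitions:

    D_i  = sum_j a_ij                      (node degree)
    CC_i = 2 E_i / (k_i (k_i - 1))         (clustering; 0 when k_i < 2)
    GE   = 1/(N(N-1)) sum_{i!=j} 1/L_ij    (1/inf = 0 for unreachable pairs)
    LE   = mean_i GE(subgraph of i's neighbours)   (0 when k_i < 2)
    L    = mean shortest path over connected pairs
    SW   = (CC / C_rand) / (L / L_rand)

with the random reference C_rand, L_rand averaged over degree-preserving
double-edge-swap rewirings of the graph itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

SPARSITY_LEVELS = (0.17, 0.22, 0.27, 0.32, 0.37, 0.42, 0.47)
METRIC_NAMES = ("degree_mean", "cc", "le", "ge", "path_length", "sw")


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.node_labels)))


@dataclass(frozen=True)
class ThresholdProfile:
    """Sparsity levels scanned per subject; metrics are averaged across them."""

    levels: tuple[float, ...] = SPARSITY_LEVELS

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if np.any(lv <= 0) or np.any(lv > 1):
            raise ValueError("sparsity levels must lie in (0, 1]")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("sparsity levels must be strictly increasing")


@dataclass(frozen=True)
class NetworkMetricSet:
    degree: np.ndarray
    cc_node: np.ndarray
    cc: float
    le: float
    ge: float
    path_length: float
    c_rand: float | None = None
    l_rand: float | None = None
    sw: float | None = None
    per_level: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {
            "degree_mean": float(self.degree.mean()),
            "cc": self.cc,
            "le": self.le,
            "ge": self.ge,
            "path_length": self.path_length,
        }
        if self.sw is not None:
            out.update({"c_rand": self.c_rand, "l_rand": self.l_rand, "sw": self.sw})
        return out


def threshold_by_sparsity(m: ConnectivityMatrix, sparsity: float) -> BinaryGraph:
    """Keep the round(sparsity * N(N-1)/2) strongest upper-triangle weights.

    Ties at the cut are broken by lexicographic (i, j) order so thresholding
    is deterministic. Warns if the resulting graph is disconnected.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    w = m.values
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    if np.all(weights == 0):
        raise ValueError("all-zero connectivity matrix: edges cannot be ranked")
    k = int(round(sparsity * n * (n - 1) / 2))
    # stable sort on (-weight, i, j): lexicographic tie-break
    order = np.lexsort((ju, iu, -weights))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    adj += adj.T
    g = BinaryGraph(adjacency=adj, sparsity=sparsity, node_labels=m.node_labels)
    if _n_components(adj) > 1:
        logger.warning(
            "graph at sparsity %.2f is disconnected (%d components)",
            sparsity, _n_components(adj),
        )
    return g


def _distances(adj: np.ndarray) -> np.ndarray:
    if adj.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(adj.astype(float), method="D", unweighted=True)


def _n_components(adj: np.ndarray) -> int:
    if adj.shape[0] == 0:
        return 0
    return _count_components(_distances(adj))


def _count_components(d: np.ndarray) -> int:
    n = d.shape[0]
    seen = np.zeros(n, bool)
    comps = 0
    for i in range(n):
        if not seen[i]:
            comps += 1
            seen |= np.isfinite(d[i])
    return comps


def node_degree(g: BinaryGraph) -> np.ndarray:
    """Row sums of the adjacency matrix."""
    return g.adjacency.sum(axis=1)


def clustering_coefficient(g: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node CC_i = 2 E_i / (k_i (k_i - 1)) and the network mean.

    Nodes with fewer than two neighbours have no neighbour pair to close
    and get CC_i = 0; the mean runs over all N nodes regardless.
    """
    a = g.adjacency
    k = a.sum(axis=1)
    # E_i = number of edges among neighbours of i = (A^3)_ii / 2
    triangles = np.diag(a @ a @ a) / 2
    cc = np.zeros(g.n_nodes)
    mask = k >= 2
    cc[mask] = 2 * triangles[mask] / (k[mask] * (k[mask] - 1))
    return cc, float(cc.mean())


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    return _efficiency_from_distances(_distances(g.adjacency))


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the efficiency of each neighbour-induced subgraph.

    Shortest paths d_jh(N_i) are computed inside the subgraph of i's
    neighbours; nodes with degree < 2 contribute 0.
    """
    a = g.adjacency
    total = 0.0
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        total += _efficiency_from_distances(_distances(a[np.ix_(nbrs, nbrs)]))
    return total / g.n_nodes


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over connected node pairs.

    Disconnected pairs are excluded from the mean (their count is logged).
    """
    d = _distances(g.adjacency)
    iu = np.triu_indices(g.n_nodes, k=1)
    vals = d[iu]
    finite = np.isfinite(vals)
    n_disc = int((~finite).sum())
    if n_disc:
        logger.info("path length: %d disconnected pairs excluded", n_disc)
    if not finite.any():
        return float("inf")
    return float(vals[finite].mean())


def random_reference(
    g: BinaryGraph, n_realizations: int = 100, seed: int = 0
) -> tuple[float, float]:
    """(C_rand, L_rand): mean clustering and path length of degree-preserving
    double-edge-swap rewirings of ``g`` (>= 10 |E| attempted swaps each).

    A graph that admits no swap (e.g. the complete graph) returns its own
    metrics with a warning.
    """
    if g.n_edges == 0:
        raise ValueError("random reference undefined for an edgeless graph")
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    max_edges = g.n_nodes * (g.n_nodes - 1) // 2
    _, c_self = clustering_coefficient(g)
    l_self = characteristic_path_length(g)
    if g.n_edges == max_edges:
        logger.warning("complete graph cannot be rewired; returning its own metrics")
        return c_self, l_self
    rng = np.random.default_rng(seed)
    base = g.to_networkx()
    cs, ls = [], []
    for _ in range(n_realizations):
        gr = base.copy()
        nswap = 10 * g.n_edges
        try:
            nx.double_edge_swap(
                gr, nswap=nswap, max_tries=100 * nswap,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXError:
            logger.warning("no double edge swap possible; using graph as its own reference")
            return c_self, l_self
        except nx.NetworkXAlgorithmError:
            logger.debug("swap budget exhausted before nswap swaps; using partial rewiring")
        adj = nx.to_numpy_array(gr, nodelist=list(g.node_labels), dtype=int)
        bg = BinaryGraph(adjacency=adj, sparsity=g.sparsity, node_labels=g.node_labels)
        cs.append(clustering_coefficient(bg)[1])
        ls.append(characteristic_path_length(bg))
    return float(np.mean(cs)), float(np.mean(ls))


def small_worldness(
    g: BinaryGraph, n_realizations: int = 100, seed: int = 0
) -> float:
    """SW = (CC / C_rand) / (L / L_rand); SW > 1 marks a small-world topology."""
    _, cc = clustering_coefficient(g)
    length = characteristic_path_length(g)
    c_rand, l_rand = random_reference(g, n_realizations, seed)
    if c_rand == 0 or length == 0 or not np.isfinite(length):
        return float("nan")
    return float((cc / c_rand) / (length / l_rand))


def graph_metrics(
    g: BinaryGraph,
    n_realizations: int = 100,
    seed: int = 0,
    with_sw: bool = True,
) -> NetworkMetricSet:
    """All metrics of one binary graph."""
    deg = node_degree(g)
    cc_node, cc = clustering_coefficient(g)
    ge = global_efficiency(g)
    le = local_efficiency(g)
    length = characteristic_path_length(g)
    if with_sw:
        c_rand, l_rand = random_reference(g, n_realizations, seed)
        sw = float("nan")
        if c_rand > 0 and np.isfinite(length) and length > 0:
            sw = float((cc / c_rand) / (length / l_rand))
        return NetworkMetricSet(deg, cc_node, cc, le, ge, length,
                                c_rand=c_rand, l_rand=l_rand, sw=sw)
    return NetworkMetricSet(deg, cc_node, cc, le, ge, length)


def metrics_over_thresholds(
    m: ConnectivityMatrix,
    profile: ThresholdProfile = ThresholdProfile(),
    n_realizations: int = 100,
    seed: int = 0,
    with_sw: bool = True,
) -> NetworkMetricSet:
    """Metrics at every sparsity level, averaged across levels.

    The mean over evenly spaced levels equals the area-under-curve summary
    up to a constant; per-level values are retained in ``per_level``.
    """
    per_level: dict[float, dict[str, float]] = {}
    rng = np.random.default_rng(seed)
    degs, ccs = [], []
    for s in profile.levels:
        g = threshold_by_sparsity(m, s)
        ms = graph_metrics(g, n_realizations, int(rng.integers(2**31 - 1)),
                           with_sw=with_sw)
        per_level[s] = ms.as_dict()
        degs.append(ms.degree)
        ccs.append(ms.cc_node)
    agg = {
        key: float(np.mean([per_level[s][key] for s in profile.levels]))
        for key in per_level[profile.levels[0]]
    }
    return NetworkMetricSet(
        degree=np.mean(degs, axis=0),
        cc_node=np.mean(ccs, axis=0),
        cc=agg["cc"],
        le=agg["le"],
        ge=agg["ge"],
        path_length=agg["path_length"],
        c_rand=agg.get("c_rand"),
        l_rand=agg.get("l_rand"),
        sw=agg.get("sw"),
        per_level=per_level,
    )
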