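"""Graph construction from connectivity matrices and complex-network metrics.

A connectivity matrix is thresholded — by intensity (keep weights strictly
above a value) or by sparsity (keep the top floor(s * N(N-1)/2) edges) —
into a weighted or binary undirected :class:`Network`.  Metrics follow the
standard definitions used for brain graphs; weighted path lengths use the
inverse weight as edge distance (appropriate when weights are correlation
strengths).  Disconnected pairs contribute zero to efficiency and are
excluded from the characteristic path length.

Fault tolerance, vulnerability, and the resilience proxy are single-node /
targeted-attack robustness measures; each lives in its own function so an
alternative definition can be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .fc import ConnectivityMatrix

__all__ = [
    "Network",
    "NetworkMetrics",
    "threshold_network",
    "compute_metrics",
    "rewire_null",
    "small_worldness",
    "metrics_group_compare",
    "global_efficiency",
    "characteristic_path_length",
]


@dataclass
class Network:
    """Undirected graph as a symmetric adjacency with threshold provenance."""

    adjacency: np.ndarray
    threshold_meta: dict = field(default_factory=dict)
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if np.max(np.abs(self.adjacency - self.adjacency.T)) > 1e-10:
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(self.adjacency, 0.0)
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency weights must be non-negative")
        if self.node_labels is None:
            self.node_labels = [f"n{k}" for k in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def is_binary(self) -> bool:
        nz = self.adjacency[self.adjacency != 0]
        return nz.size == 0 or np.all(nz == 1.0)

    def graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        # distance = 1/weight for weighted shortest paths
        for _, _, d in g.edges(data=True):
            d["distance"] = 1.0 / d["weight"]
        return g


@dataclass
class NetworkMetrics:
    global_: dict
    nodal: pd.DataFrame


def threshold_network(
    cm: ConnectivityMatrix | np.ndarray,
    method: str = "sparsity",
    value: float = 0.2,
    binarize: bool = True,
    negatives: str = "discard",
    node_labels: list[str] | None = None,
) -> Network:
    """Threshold a symmetric connectivity matrix into a graph.

    ``intensity`` keeps edges with weight strictly greater than ``value``;
    ``sparsity`` keeps the top floor(s * N(N-1)/2) edges by weight, ties
    broken in (i, j) lexicographic order.  Negative weights are discarded
    or absolute-valued (``negatives``) before thresholding.
    """
    if isinstance(cm, ConnectivityMatrix):
        w = cm.values.copy()
        node_labels = node_labels or cm.node_labels
    else:
        w = np.asarray(cm, dtype=np.float64).copy()
    n = w.shape[0]
    np.fill_diagonal(w, 0.0)
    if negatives == "discard":
        w[w < 0] = 0.0
    elif negatives == "absolute":
        w = np.abs(w)
    else:
        raise ValueError("negatives must be 'discard' or 'absolute'")

    adj = np.zeros_like(w)
    iu = np.triu_indices(n, k=1)
    weights = w[iu]
    if method == "intensity":
        keep = weights > value
        if not keep.any():
            warnings.warn("intensity threshold leaves an empty graph")
    elif method == "sparsity":
        if not 0.0 < value <= 1.0:
            raise ValueError("sparsity must be in (0, 1]")
        n_keep = int(np.floor(value * n * (n - 1) / 2))
        if n_keep == 0:
            raise ValueError("sparsity threshold yields 0 edges")
        # sort by weight descending, ties by (i, j) lexicographic order;
        # the triu_indices enumeration is already lexicographic, and a
        # stable sort on -weight preserves it within ties
        order = np.argsort(-weights, kind="stable")[:n_keep]
        keep = np.zeros_like(weights, dtype=bool)
        keep[order] = True
        keep &= weights > 0  # never admit zero/absent edges
    else:
        raise ValueError("method must be 'intensity' or 'sparsity'")
    kept_w = np.where(keep, 1.0 if binarize else weights, 0.0)
    adj[iu] = kept_w
    adj = adj + adj.T
    meta = {"method": method, "value": value, "binarized": binarize,
            "negatives": negatives, "n_edges": int(keep.sum())}
    return Network(adj, meta, node_labels)


def _distance_matrix(net: Network) -> np.ndarray:
    """All-pairs shortest-path distances; inf for disconnected pairs.

    Binary graphs use hop counts; weighted graphs use 1/weight edge lengths.
    """
    g = net.graph()
    n = net.n_nodes
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    weight = None if net.is_binary else "distance"
    for src, lengths in nx.shortest_path_length(g, weight=weight):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


def characteristic_path_length(net: Network) -> float:
    """Mean finite shortest-path distance over ordered pairs i != j."""
    dist = _distance_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        return np.inf
    return float(dist[finite].mean())


def global_efficiency(net: Network, dist: np.ndarray | None = None) -> float:
    """Mean of 1/d(i, j) over ordered pairs; disconnected pairs add 0."""
    if net.n_nodes < 2:
        return 0.0
    if dist is None:
        dist = _distance_matrix(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].mean())


def _subnetwork(net: Network, keep: np.ndarray) -> Network:
    return Network(net.adjacency[np.ix_(keep, keep)], dict(net.threshold_meta))


def node_removal_efficiencies(net: Network) -> np.ndarray:
    """Global efficiency of the graph with each single node removed."""
    n = net.n_nodes
    out = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        out[i] = global_efficiency(_subnetwork(net, keep))
    return out


def fault_tolerance(net: Network) -> float:
    """Mean over nodes of E_{-i} / E: how much efficiency survives a failure."""
    e = global_efficiency(net)
    if e == 0:
        return 0.0
    return float(np.mean(node_removal_efficiencies(net) / e))


def vulnerability(net: Network) -> float:
    """Max over nodes of (E - E_{-i}) / E: worst single-node efficiency loss."""
    e = global_efficiency(net)
    if e == 0:
        return 0.0
    return float(np.max((e - node_removal_efficiencies(net)) / e))


def resilience_auc(net: Network) -> float:
    """Area under the largest-component fraction vs fraction-removed curve
    for targeted removal of the currently highest-degree node (recomputed
    each step); in [0, 1], higher = more attack-resilient."""
    adj = net.adjacency.copy() != 0
    n = net.n_nodes
    alive = np.ones(n, dtype=bool)
    fractions = []
    for _ in range(n + 1):
        if alive.any():
            g = nx.from_numpy_array(adj[np.ix_(alive, alive)])
            if g.number_of_nodes():
                largest = max((len(c) for c in nx.connected_components(g)), default=0)
            else:
                largest = 0
            fractions.append(largest / n)
        else:
            fractions.append(0.0)
        if not alive.any():
            break
        degrees = adj[np.ix_(alive, alive)].sum(axis=1)
        victim = np.flatnonzero(alive)[int(np.argmax(degrees))]
        alive[victim] = False
    return float(np.trapezoid(fractions, dx=1.0 / n))


def compute_metrics(net: Network) -> NetworkMetrics:
    """Global and nodal complex-network metrics of one thresholded graph."""
    n = net.n_nodes
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if net.n_edges == 0:
        raise ValueError("empty graph")
    g = net.graph()
    dist = _distance_matrix(net)
    weight_key = None if net.is_binary else "weight"

    clustering = np.array([nx.clustering(g, weight=weight_key)[i] for i in range(n)])
    betweenness_dict = nx.betweenness_centrality(
        g, normalized=True, weight=None if net.is_binary else "distance"
    )
    betweenness = np.array([betweenness_dict[i] for i in range(n)])
    degree_binary = (net.adjacency != 0).sum(axis=1).astype(float)
    degree_weighted = net.adjacency.sum(axis=1)
    nbr_deg_dict = nx.average_neighbor_degree(g, weight=weight_key)
    neighbor_degree = np.array([nbr_deg_dict[i] for i in range(n)])

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(net.adjacency[i] != 0)
        if len(nbrs) >= 2:
            local_eff[i] = global_efficiency(_subnetwork(net, nbrs))

    try:
        # regular graphs have zero degree variance -> NaN, not an error
        with np.errstate(invalid="ignore", divide="ignore"):
            assort = float(nx.degree_assortativity_coefficient(g))
    except (ValueError, ZeroDivisionError):
        assort = np.nan

    e_glob = global_efficiency(net, dist)
    global_ = {
        "characteristic_path_length": characteristic_path_length(net),
        "global_efficiency": e_glob,
        "mean_clustering": float(clustering.mean()),
        "local_efficiency": float(local_eff.mean()),
        "transitivity": float(nx.transitivity(g)),
        "assortativity": assort,
        "fault_tolerance": fault_tolerance(net),
        "vulnerability": vulnerability(net),
        "resilience_auc": resilience_auc(net),
    }
    nodal = pd.DataFrame({
        "degree_binary": degree_binary,
        "degree_weighted": degree_weighted,
        "neighbor_degree": neighbor_degree,
        "clustering": clustering,
        "betweenness": betweenness,
        "local_efficiency": local_eff,
    }, index=net.node_labels)
    return NetworkMetrics(global_=global_, nodal=nodal)


def rewire_null(net: Network, swaps_per_edge: int = 10, seed: int = 0) -> Network:
    """Degree-preserving null model by double-edge swaps (seeded)."""
    g = nx.from_numpy_array((net.adjacency != 0).astype(float))
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("graph too small to rewire")
    nswap = swaps_per_edge * m
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                            seed=int(seed))
    except nx.NetworkXAlgorithmError:
        warnings.warn("double-edge swap hit the retry cap; null is partially rewired")
    adj = nx.to_numpy_array(g)
    return Network(adj, {"null_of": net.threshold_meta, "seed": seed})


def small_worldness(net: Network, n_null: int = 100, swaps_per_edge: int = 10,
                    seed: int = 0) -> dict:
    """Small-world coefficient sigma = (C/C_null) / (L/L_null).

    C is the mean clustering coefficient and L the characteristic path
    length; null values average ``n_null`` degree-preserving rewired graphs.
    Requires a connected input graph.
    """
    dist = _distance_matrix(net)
    if not np.all(np.isfinite(dist)):
        raise ValueError("graph is disconnected; lower the threshold")
    g = net.graph()
    c = float(np.mean(list(nx.clustering(g).values())))
    length = characteristic_path_length(net)
    c_null, l_null = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_null):
        null = rewire_null(net, swaps_per_edge, seed=int(rng.integers(2**31)))
        gn = null.graph()
        c_null.append(float(np.mean(list(nx.clustering(gn).values()))))
        l_null.append(characteristic_path_length(null))
    c_ratio = c / float(np.mean(c_null))
    l_ratio = length / float(np.mean(l_null))
    return {"sigma": c_ratio / l_ratio, "c_ratio": c_ratio, "l_ratio": l_ratio,
            "clustering": c, "path_length": length}


def metrics_group_compare(
    table: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Two-sample t-tests per (metric, threshold) across subjects.

    ``table`` is long format with columns (subject, threshold, metric,
    value); ``groups`` maps subject -> group label (exactly two labels).
    Returns one row per (metric, threshold) with t, df, and two-sided p.
    """
    groups = pd.Series(dict(groups))
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    rows = []
    for (metric, thr), sub in table.groupby(["metric", "threshold"]):
        a = sub.loc[sub["subject"].map(groups) == labels[0], "value"].to_numpy()
        b = sub.loc[sub["subject"].map(groups) == labels[1], "value"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"fewer than 2 subjects per group for {metric}@{thr}")
        t, p = sps.ttest_ind(a, b)
        rows.append({"metric": metric, "threshold": thr, "t": float(t),
                     "df": len(a) + len(b) - 2, "p": float(p)})
    return pd.DataFrame(rows)
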