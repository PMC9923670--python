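"""Brain-graph construction, topology metrics, and permutation testing.

Graphs are weighted and undirected, one per treatment group, with one
node per atlas region.  Because shortest paths are undefined for
negative weights, topology metrics operate on the absolute-value or
thresholded graph; the signed graph is retained for edge-level display
only.  Group-level networks admit no subject-level metric, so between-
group differences are tested by permuting subject *labels* and
recomputing both group matrices, graphs and metrics per shuffle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import GroupConnectivity, rank_correlation_matrix
from .tables import UptakeTable

SCHEMES = ("signed_rho", "abs_rho", "thresholded")
METRICS = ("degree", "betweenness", "local_efficiency")

#: default |rho| threshold for the thresholded scheme
DEFAULT_THRESHOLD = 0.5


def _threshold_adjacency(rho: np.ndarray, threshold, n: int | None) -> np.ndarray:
    """Boolean suprathreshold adjacency from a correlation matrix.

    ``threshold`` is a float (keep |rho| >= t), the string ``"significant"``
    (keep edges whose own-group correlation is nonzero at p < 0.05 via the
    Fisher-z normal approximation; needs the group size n), or
    ``("top_k", k)`` for a density-matched strongest-k rule.
    """
    a = np.abs(np.asarray(rho, float))
    np.fill_diagonal(a, 0.0)
    a = np.where(np.isfinite(a), a, 0.0)
    if isinstance(threshold, (int, float)):
        adj = a >= float(threshold)
    elif threshold == "significant":
        if n is None or n <= 3:
            raise ValueError("'significant' thresholding needs the group size n > 3")
        crit = stats.norm.isf(0.025) * np.sqrt(1.0 / (n - 3))
        adj = np.arctanh(np.clip(a, 0.0, 1.0 - 1e-7)) >= crit
    elif isinstance(threshold, tuple) and threshold[0] == "top_k":
        k = int(threshold[1])
        iu, ju = np.triu_indices(a.shape[0], k=1)
        order = np.argsort(a[iu, ju])[::-1][:k]
        adj = np.zeros_like(a, bool)
        adj[iu[order], ju[order]] = True
        adj = adj | adj.T
    else:
        raise ValueError(f"unknown threshold rule {threshold!r}")
    np.fill_diagonal(adj, False)
    return adj & adj.T


def build_graph(
    conn: GroupConnectivity,
    scheme: str = "thresholded",
    threshold=DEFAULT_THRESHOLD,
) -> nx.Graph:
    """Weighted undirected graph from a group connectivity matrix.

    signed_rho keeps every off-diagonal rho as a signed weight; abs_rho
    takes |rho|; thresholded keeps |rho| at or above the threshold rule.
    Undefined (NaN) correlations never become edges.  A threshold that
    removes all edges yields an empty graph, not a failure.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    codes = conn.region_set.codes
    rho = np.asarray(conn.rho, float)
    g = nx.Graph(scheme=scheme, threshold=repr(threshold), group=conn.group)
    g.add_nodes_from(codes)
    iu, ju = np.triu_indices(len(codes), k=1)
    if scheme == "thresholded":
        adj = _threshold_adjacency(rho, threshold, conn.n)
        keep = adj[iu, ju]
    else:
        keep = np.isfinite(rho[iu, ju])
        if scheme == "signed_rho":
            keep &= rho[iu, ju] != 0.0
        else:
            keep &= np.abs(rho[iu, ju]) > 0.0
    for i, j in zip(iu[keep], ju[keep]):
        w = rho[i, j] if scheme == "signed_rho" else abs(rho[i, j])
        g.add_edge(codes[i], codes[j], weight=float(w))
    if g.number_of_edges() == 0 and len(codes) > 1:
        warnings.warn(
            f"graph for group {conn.group!r} has no edges under scheme "
            f"{scheme!r} (threshold {threshold!r})",
            stacklevel=2,
        )
    return g


def _require_nonnegative(graph: nx.Graph, what: str) -> None:
    if graph.graph.get("scheme") == "signed_rho" or any(
        d["weight"] < 0 for _, _, d in graph.edges(data=True)
    ):
        raise ValueError(
            f"{what} needs non-negative edge weights; build the graph with "
            "scheme='abs_rho' or 'thresholded' (shortest paths are undefined "
            "for signed correlations)"
        )


def node_degree(graph: nx.Graph) -> dict[str, int]:
    """Suprathreshold incident-edge count per node (unweighted)."""
    return {node: int(d) for node, d in graph.degree()}


def node_strength(graph: nx.Graph) -> dict[str, float]:
    """Sum of incident edge weights per node."""
    return {node: float(s) for node, s in graph.degree(weight="weight")}


def betweenness(graph: nx.Graph, normalized: bool = True,
                weighted: bool = True) -> dict[str, float]:
    """Betweenness centrality: fraction of shortest paths through a node.

    Weighted mode uses distance = 1/weight (strong correlations are
    short); binary mode ignores weights.  Exact Brandes accumulation
    over all path multiplicities.
    """
    _require_nonnegative(graph, "betweenness")
    if weighted:
        for u, v, d in graph.edges(data=True):
            d["distance"] = 1.0 / d["weight"] if d["weight"] > 0 else np.inf
        return dict(
            nx.betweenness_centrality(graph, normalized=normalized, weight="distance")
        )
    return dict(nx.betweenness_centrality(graph, normalized=normalized, weight=None))


def _hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop counts of a boolean adjacency matrix.

    Breadth-first expansion by boolean matrix products; unreachable
    pairs stay at +inf.
    """
    k = adj.shape[0]
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    reach = adj | np.eye(k, dtype=bool)
    hops = 1
    while True:
        new_reach = reach @ adj | reach
        frontier = new_reach & ~reach
        if not frontier.any():
            break
        hops += 1
        dist[frontier] = hops
        reach = new_reach
    return dist


def _local_efficiency_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Per-node local efficiency of a boolean adjacency matrix."""
    r = adj.shape[0]
    out = np.zeros(r)
    for v in range(r):
        nbrs = np.flatnonzero(adj[v])
        k = len(nbrs)
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = _hop_distances(sub)
        mask = (d > 0) & np.isfinite(d)
        out[v] = (1.0 / d[mask]).sum() / (k * (k - 1))
    return out


def local_efficiency(graph: nx.Graph) -> dict[str, float]:
    """Per-node local efficiency with the binary distance convention.

    For node v: the global efficiency (mean inverse shortest-path
    distance over ordered pairs) of the subgraph induced by v's
    neighbours.  Nodes with fewer than two neighbours score 0.  Values
    lie in [0, 1]; 1 means every pair of neighbours is directly linked.
    """
    _require_nonnegative(graph, "local efficiency")
    nodes = list(graph.nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight=None).astype(bool)
    values = _local_efficiency_from_adjacency(adj)
    return {node: float(v) for node, v in zip(nodes, values)}


def graph_density(graph: nx.Graph) -> float:
    return nx.density(graph)


def node_metrics(graph: nx.Graph) -> pd.DataFrame:
    """Long-format table of degree, betweenness and local efficiency."""
    deg = node_degree(graph)
    btw = betweenness(graph)
    eff = local_efficiency(graph)
    rows = []
    for node in graph.nodes:
        rows.append((node, "degree", float(deg[node])))
        rows.append((node, "betweenness", btw[node]))
        rows.append((node, "local_efficiency", eff[node]))
    df = pd.DataFrame(rows, columns=["node", "metric", "value"])
    df.insert(0, "group", graph.graph.get("group", ""))
    return df


# ---------------------------------------------------------------------------
# Permutation testing


@dataclass
class PermutationResult:
    """Permutation-null comparison of one metric between two groups."""

    metric: str
    group_1: str
    group_2: str
    n_permutations: int
    seed: int
    table: pd.DataFrame  # node, observed_diff, null_lo, null_median, null_hi, p

    def p_value(self, node: str) -> float:
        return float(self.table.set_index("node").loc[node, "p"])


def _metric_vector(
    rho: np.ndarray, codes: list[str], metric: str, scheme: str, threshold, n: int
) -> np.ndarray:
    if scheme == "thresholded":
        adj = _threshold_adjacency(rho, threshold, n)
    else:
        a = np.abs(np.where(np.isfinite(rho), rho, 0.0))
        np.fill_diagonal(a, 0.0)
        adj = a > 0
    if metric == "degree":
        return adj.sum(axis=1).astype(float)
    if metric == "local_efficiency":
        return _local_efficiency_from_adjacency(adj)
    g = _graph_from_matrix(rho, codes, scheme, threshold, n)
    values = betweenness(g)
    return np.array([values[c] for c in codes], float)


def _graph_from_matrix(rho, codes, scheme, threshold, n) -> nx.Graph:
    conn = GroupConnectivity("", n, np.asarray(rho, float),
                             region_set=_AdHocRegionSet(codes))
    return build_graph(conn, scheme=scheme, threshold=threshold)


class _AdHocRegionSet:
    """Minimal stand-in carrying only the ordered codes (internal use)."""

    def __init__(self, codes: list[str]):
        self.codes = list(codes)


def permutation_test(
    table: UptakeTable,
    group_1: str,
    group_2: str,
    metric: str = "degree",
    n_perm: int = 5000,
    seed: int = 0,
    scheme: str = "thresholded",
    threshold=DEFAULT_THRESHOLD,
    nodes: list[str] | None = None,
) -> PermutationResult:
    """Subject-label permutation test of a per-node topology metric.

    The observed statistic is metric(group 1) - metric(group 2) per
    node.  Each permutation shuffles the pooled subjects' group labels,
    recomputes both group Spearman matrices, rebuilds the graphs and
    recomputes the metric.  Two-sided add-one p-value:
    p = (1 + #{|null| >= |observed|}) / (n_perm + 1), so p is never 0
    and is floored at 1/(n_perm + 1).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    if scheme == "signed_rho":
        raise ValueError("topology metrics need scheme 'abs_rho' or 'thresholded'")
    x1 = table.group_values(group_1)
    x2 = table.group_values(group_2)
    n1, n2 = len(x1), len(x2)
    if min(n1, n2) < 4:
        raise ValueError(
            f"groups too small to permute meaningfully (n={n1}, {n2}; need >= 4)"
        )
    codes = table.region_set.codes
    pooled = np.vstack([x1, x2])

    def metric_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ra = rank_correlation_matrix(a)
        rb = rank_correlation_matrix(b)
        return (
            _metric_vector(ra, codes, metric, scheme, threshold, len(a))
            - _metric_vector(rb, codes, metric, scheme, threshold, len(b))
        )

    observed = metric_diff(x1, x2)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(codes)))
    for k in range(n_perm):
        perm = rng.permutation(n1 + n2)
        null[k] = metric_diff(pooled[perm[:n1]], pooled[perm[n1:]])

    exceed = (np.abs(null) >= np.abs(observed)[None, :] - 1e-12).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    lo, med, hi = np.percentile(null, [2.5, 50.0, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "node": codes,
            "observed_diff": observed,
            "null_lo": lo,
            "null_median": med,
            "null_hi": hi,
            "p": p,
        }
    )
    if nodes is not None:
        out = out[out["node"].isin(nodes)].reset_index(drop=True)
    return PermutationResult(metric, group_1, group_2, n_perm, seed, out)
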