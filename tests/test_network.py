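import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metaconn.connectivity import GroupConnectivity, spearman_matrix
from metaconn.network import (
    betweenness,
    build_graph,
    local_efficiency,
    node_degree,
    node_metrics,
    node_strength,
    permutation_test,
    _metric_vector,
    _threshold_adjacency,
)
from metaconn.regions import Region, RegionSet
from metaconn.synthetic import generate_cohort, hub_degradation_config
from metaconn.tables import UptakeTable


def _regions(n):
    return RegionSet(
        [Region(f"n{k}", f"node {k}", "L", "cortical", k + 1) for k in range(n)]
    )


def _conn(rho, n=10):
    rho = np.asarray(rho, float)
    return GroupConnectivity("G", n, rho, _regions(rho.shape[0]))


def _random_conn(rng, size, n=10):
    m = rng.uniform(-1, 1, (size, size))
    rho = (m + m.T) / 2
    np.fill_diagonal(rho, 1.0)
    return _conn(rho, n)


# -- brute-force oracles ----------------------------------------------------


def brute_betweenness(graph):
    """Exhaustive shortest-path enumeration (feasible for <= 8 nodes)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    acc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        best = np.inf
        for path in nx.all_simple_paths(graph, s, t):
            length = sum(
                1.0 / graph[u][v]["weight"] for u, v in zip(path, path[1:])
            )
            if length < best - 1e-12:
                best, paths = length, [path]
            elif abs(length - best) <= 1e-12:
                paths.append(path)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            acc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: acc[v] / norm for v in nodes}


def brute_local_efficiency(graph):
    """Floyd-Warshall on each neighbour-induced binary subgraph."""
    out = {}
    for v in graph.nodes:
        nbrs = list(graph.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        dist = np.full((k, k), np.inf)
        np.fill_diagonal(dist, 0.0)
        for i, j in itertools.combinations(range(k), 2):
            if graph.has_edge(nbrs[i], nbrs[j]):
                dist[i, j] = dist[j, i] = 1.0
        for m in range(k):
            dist = np.minimum(dist, dist[:, [m]] + dist[[m], :])
        inv = 1.0 / dist[(dist > 0) & np.isfinite(dist)]
        out[v] = inv.sum() / (k * (k - 1))
    return out


# -- construction -----------------------------------------------------------


class TestBuildGraph:
    def test_identity_matrix_any_threshold_no_edges(self):
        conn = _conn(np.eye(5))
        with pytest.warns(UserWarning, match="no edges"):
            g = build_graph(conn, "thresholded", 0.1)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5

    def test_all_ones_matrix_complete_graph(self):
        conn = _conn(np.ones((6, 6)))
        g = build_graph(conn, "thresholded", 0.5)
        assert g.number_of_edges() == 15
        assert nx.density(g) == 1.0

    def test_threshold_keeps_counted_edges(self):
        rng = np.random.default_rng(42)
        conn = _random_conn(rng, 10)
        iu, ju = np.triu_indices(10, k=1)
        expected = int(np.count_nonzero(np.abs(conn.rho[iu, ju]) >= 0.5))
        g = build_graph(conn, "thresholded", 0.5)
        assert g.number_of_edges() == expected

    def test_signed_scheme_keeps_negative_weights(self):
        rho = np.array([[1.0, -0.8], [-0.8, 1.0]])
        g = build_graph(_conn(rho), "signed_rho")
        assert g["n0"]["n1"]["weight"] == -0.8

    def test_abs_scheme_all_nonnegative(self):
        rng = np.random.default_rng(7)
        g = build_graph(_random_conn(rng, 8), "abs_rho")
        assert all(d["weight"] >= 0 for _, _, d in g.edges(data=True))

    def test_nan_edges_never_created(self):
        rho = np.ones((3, 3))
        rho[0, 1] = rho[1, 0] = np.nan
        g = build_graph(_conn(rho), "abs_rho")
        assert not g.has_edge("n0", "n1")
        assert g.has_edge("n0", "n2")

    def test_significant_threshold_rule(self):
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = 0.95
        rho[2, 3] = rho[3, 2] = 0.2
        g = build_graph(_conn(rho, n=10), "thresholded", "significant")
        assert g.has_edge("n0", "n1")
        assert not g.has_edge("n2", "n3")

    def test_top_k_rule_density_matched(self):
        rng = np.random.default_rng(3)
        g = build_graph(_random_conn(rng, 9), "thresholded", ("top_k", 7))
        assert g.number_of_edges() == 7


class TestMetrics:
    def test_complete_graph_degrees(self):
        g = build_graph(_conn(np.ones((5, 5))), "thresholded", 0.5)
        assert set(node_degree(g).values()) == {4}

    def test_star_graph_degrees_and_center_betweenness(self):
        rho = np.eye(6)
        rho[0, 1:] = rho[1:, 0] = 0.9
        g = build_graph(_conn(rho), "thresholded", 0.5)
        deg = node_degree(g)
        assert deg["n0"] == 5
        assert all(deg[f"n{k}"] == 1 for k in range(1, 6))
        btw = betweenness(g)
        assert btw["n0"] == pytest.approx(1.0)
        assert btw["n1"] == 0.0
        # star center's neighbours are mutually disconnected
        assert local_efficiency(g)["n0"] == 0.0

    def test_path_graph_betweenness(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.9
        rho[1, 2] = rho[2, 1] = 0.9
        btw = betweenness(build_graph(_conn(rho), "thresholded", 0.5))
        assert btw["n1"] == pytest.approx(1.0)
        assert btw["n0"] == btw["n2"] == 0.0

    def test_complete_graph_betweenness_zero_efficiency_one(self):
        g = build_graph(_conn(np.ones((6, 6))), "thresholded", 0.5)
        assert all(v == 0.0 for v in betweenness(g).values())
        assert all(v == pytest.approx(1.0) for v in local_efficiency(g).values())

    def test_signed_graph_rejected_for_metrics(self):
        rho = np.array([[1.0, -0.8], [-0.8, 1.0]])
        g = build_graph(_conn(rho), "signed_rho")
        for fn in (betweenness, local_efficiency):
            with pytest.raises(ValueError, match="scheme"):
                fn(g)

    def test_degree_matches_adjacency_row_sums(self):
        rng = np.random.default_rng(11)
        conn = _random_conn(rng, 12)
        g = build_graph(conn, "thresholded", 0.4)
        adj = _threshold_adjacency(conn.rho, 0.4, conn.n)
        for i, code in enumerate(conn.region_set.codes):
            assert node_degree(g)[code] == adj[i].sum()

    @pytest.mark.parametrize("seed", range(8))
    def test_weighted_betweenness_matches_exhaustive_paths(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(5, 8))
        g = build_graph(_random_conn(rng, size), "thresholded", 0.3)
        ours = betweenness(g)
        oracle = brute_betweenness(g)
        for v in g.nodes:
            assert ours[v] == pytest.approx(oracle[v], abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_local_efficiency_matches_floyd_warshall(self, seed):
        rng = np.random.default_rng(100 + seed)
        size = int(rng.integers(5, 9))
        g = build_graph(_random_conn(rng, size), "thresholded", 0.3)
        ours = local_efficiency(g)
        oracle = brute_local_efficiency(g)
        for v in g.nodes:
            assert ours[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_metrics_invariant_to_node_relabeling(self):
        rng = np.random.default_rng(21)
        conn = _random_conn(rng, 9)
        perm = rng.permutation(9)
        permuted = GroupConnectivity(
            "G", conn.n, conn.rho[np.ix_(perm, perm)],
            RegionSet([conn.region_set.regions[i] for i in perm]),
        )
        g1 = build_graph(conn, "thresholded", 0.4)
        g2 = build_graph(permuted, "thresholded", 0.4)
        for fn in (node_degree, betweenness, local_efficiency):
            a, b = fn(g1), fn(g2)
            assert a == pytest.approx(b)

    def test_degree_monotone_in_threshold(self):
        rng = np.random.default_rng(33)
        conn = _random_conn(rng, 15)
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8):
            total = sum(node_degree(build_graph(conn, "thresholded", t)).values())
            if prev is not None:
                assert total <= prev
            prev = total

    def test_node_metrics_long_format(self, cohort):
        conn = spearman_matrix(cohort, "pre_VEH")
        df = node_metrics(build_graph(conn))
        assert set(df["metric"]) == {"degree", "betweenness", "local_efficiency"}
        assert len(df) == 28 * 3
        eff = df[df.metric == "local_efficiency"]["value"]
        assert ((eff >= 0) & (eff <= 1)).all()

    def test_strength_equals_weight_sums(self):
        rng = np.random.default_rng(2)
        conn = _random_conn(rng, 6)
        g = build_graph(conn, "abs_rho")
        for i, code in enumerate(conn.region_set.codes):
            expected = np.abs(np.delete(conn.rho[i], i)).sum()
            assert node_strength(g)[code] == pytest.approx(expected)


class TestPermutationTest:
    def test_identical_groups_p_one_everywhere(self, region_set):
        rng = np.random.default_rng(9)
        values = 1 + 0.1 * rng.standard_normal((8, 28))
        rows = []
        for g in ("A", "B"):
            for i in range(8):
                rows.append([f"{g}{i}", g, *values[i]])
        df = pd.DataFrame(
            rows, columns=["subject_id", "group", *region_set.codes]
        )
        table = UptakeTable(df, region_set)
        res = permutation_test(table, "A", "B", n_perm=200, seed=0)
        assert np.allclose(res.table["observed_diff"], 0.0)
        assert np.allclose(res.table["p"], 1.0)

    def test_p_floor_is_add_one_bound(self):
        table = generate_cohort(hub_degradation_config(seed=5))
        res = permutation_test(
            table, "A", "B", metric="degree", n_perm=200, seed=1, threshold=0.55
        )
        assert (res.table["p"] >= 1.0 / 201).all()
        assert (res.table["p"] <= 1.0).all()

    def test_hub_degradation_detected(self):
        table = generate_cohort(hub_degradation_config(seed=2))
        res = permutation_test(
            table, "A", "B", metric="degree", n_perm=500, seed=3, threshold=0.55
        )
        assert res.p_value("R_AntHip") < 0.05
        assert res.table.set_index("node")["observed_diff"]["R_AntHip"] > 0

    def test_fast_degree_path_matches_graph_route(self, cohort):
        conn = spearman_matrix(cohort, "QA_VEH")
        fast = _metric_vector(
            conn.rho, conn.region_set.codes, "degree", "thresholded", 0.5, conn.n
        )
        g = build_graph(conn, "thresholded", 0.5)
        slow = [node_degree(g)[c] for c in conn.region_set.codes]
        assert np.array_equal(fast, slow)

    def test_deterministic_given_seed(self, cohort):
        a = permutation_test(cohort, "pre_VEH", "QA_VEH", n_perm=150, seed=4)
        b = permutation_test(cohort, "pre_VEH", "QA_VEH", n_perm=150, seed=4)
        assert a.table.equals(b.table)

    def test_rejects_bad_inputs(self, cohort):
        with pytest.raises(ValueError, match="metric"):
            permutation_test(cohort, "pre_VEH", "QA_VEH", metric="clustering")
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(cohort, "pre_VEH", "QA_VEH", n_perm=10)
        with pytest.raises(ValueError, match="abs_rho"):
            permutation_test(
                cohort, "pre_VEH", "QA_VEH", n_perm=100, scheme="signed_rho"
            )
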