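"""Small-world graph metrics against brute-force and networkx oracles."""

import numpy as np
import networkx as nx
import pytest

from eegfc import (
    BANDS,
    ConnectivityMatrix,
    binarize,
    characteristic_path_length,
    clustering_coefficient,
    fdr_correct,
    graph_metrics,
    group_node_ttest,
    random_reference,
    small_world_index,
    sweep_thresholds,
    threshold_sweep,
)


# -- independent oracles ------------------------------------------------------

def brute_clustering(adj):
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:])
        cs.append(2.0 * links / (k * (k - 1)))
    return np.array(cs)


def brute_path_length(adj):
    """Floyd-Warshall over connected ordered pairs."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    return d[finite].mean()


def random_adj(rng, n, p):
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a | a.T


# -- tests --------------------------------------------------------------------

class TestBinarize:
    def test_all_ones_complete_graph(self):
        g = binarize(np.ones((5, 5)), 0.5)
        assert g.n_edges == 10
        assert np.all(np.diag(g.adjacency) == 0)

    def test_value_exactly_at_threshold_is_no_edge(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        assert binarize(m, 0.5).n_edges == 0  # strict inequality

    def test_hand_enumerated_edge_set(self):
        m = np.zeros((4, 4))
        vals = {(0, 1): 0.2, (0, 2): 0.6, (0, 3): 0.9, (1, 2): 0.4,
                (1, 3): 0.55, (2, 3): 0.1}
        for (i, j), v in vals.items():
            m[i, j] = m[j, i] = v
        g = binarize(m, 0.5)
        edges = {(i, j) for i in range(4) for j in range(i + 1, 4)
                 if g.adjacency[i, j]}
        assert edges == {(0, 2), (0, 3), (1, 3)}

    def test_threshold_domain(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                binarize(np.ones((3, 3)), bad)


class TestClusteringAndPathLength:
    def test_complete_graph_K4(self):
        adj = (1 - np.eye(4)).astype(np.uint8)
        _, c = clustering_coefficient(adj)
        assert c == pytest.approx(1.0)
        assert characteristic_path_length(adj) == pytest.approx(1.0)

    def test_star_graph_no_triangles(self):
        adj = np.zeros((6, 6), dtype=np.uint8)
        adj[0, 1:] = adj[1:, 0] = 1
        _, c = clustering_coefficient(adj)
        assert c == pytest.approx(0.0)

    def test_path_graph_P4(self):
        adj = np.zeros((4, 4), dtype=np.uint8)
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1
        assert characteristic_path_length(adj) == pytest.approx(10 / 6)

    def test_ring_C6(self):
        adj = np.zeros((6, 6), dtype=np.uint8)
        for i in range(6):
            adj[i, (i + 1) % 6] = adj[(i + 1) % 6, i] = 1
        assert characteristic_path_length(adj) == pytest.approx(1.8)

    def test_matches_brute_force_on_small_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(2, 7)
            adj = random_adj(rng, n, rng.uniform(0.2, 0.9))
            node_c, c = clustering_coefficient(adj)
            np.testing.assert_allclose(node_c, brute_clustering(adj), atol=1e-12)
            if adj.sum() > 0:
                assert characteristic_path_length(adj) == pytest.approx(
                    brute_path_length(adj))

    def test_matches_networkx_on_medium_graph(self):
        rng = np.random.default_rng(3)
        adj = random_adj(rng, 40, 0.15)
        g = nx.from_numpy_array(adj)
        node_c, c = clustering_coefficient(adj)
        assert c == pytest.approx(nx.average_clustering(g))
        if nx.is_connected(g):
            assert characteristic_path_length(adj) == pytest.approx(
                nx.average_shortest_path_length(g))

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            characteristic_path_length(np.zeros((4, 4), dtype=np.uint8))


class TestRandomReference:
    def test_complete_graph_unique_reference(self):
        adj = (1 - np.eye(5)).astype(np.uint8)
        cr, lr = random_reference(adj, n_random=5, seed=0)
        assert cr == pytest.approx(1.0)
        assert lr == pytest.approx(1.0)

    def test_single_edge_reference_has_no_triangles(self):
        adj = np.zeros((6, 6), dtype=np.uint8)
        adj[0, 1] = adj[1, 0] = 1
        cr, _ = random_reference(adj, n_random=5, seed=0)
        assert cr == pytest.approx(0.0)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(1)
        adj = random_adj(rng, 20, 0.2)
        a = random_reference(adj, n_random=20, seed=5)
        b = random_reference(adj, n_random=20, seed=5)
        c = random_reference(adj, n_random=20, seed=6)
        assert a == b
        assert a != c

    def test_references_match_edge_count(self):
        # Cr of G(n, m) references approximates the density m / C(n,2)
        rng = np.random.default_rng(2)
        adj = random_adj(rng, 30, 0.3)
        m = adj.sum() // 2
        cr, _ = random_reference(adj, n_random=50, seed=0)
        density = m / (30 * 29 / 2)
        assert cr == pytest.approx(density, rel=0.25)


class TestSmallWorld:
    def test_identity_ratios(self):
        assert small_world_index(0.5, 2.0, 0.5, 2.0) == (1.0, 1.0, 1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            small_world_index(0.5, 2.0, 0.0, 2.0)

    def test_watts_strogatz_is_small_world(self):
        vals = []
        for seed in range(5):
            g = nx.watts_strogatz_graph(100, 4, 0.05, seed=seed)
            gm = graph_metrics(nx.to_numpy_array(g), n_random=20, seed=seed)
            vals.append(gm.S)
        assert np.mean(vals) > 1.0
        assert min(vals) > 1.0

    def test_uniform_random_graph_S_near_one(self):
        vals = []
        for seed in range(10):
            g = nx.gnm_random_graph(100, 200, seed=seed)
            gm = graph_metrics(nx.to_numpy_array(g), n_random=20, seed=seed)
            vals.append(gm.S)
        assert abs(np.mean(vals) - 1.0) < 0.2

    def test_lattice_gamma_exceeds_random_gamma(self):
        lattice_gammas, random_gammas = [], []
        for seed in range(5):
            ring = nx.watts_strogatz_graph(60, 4, 0.0, seed=seed)  # pure lattice
            rnd = nx.gnm_random_graph(60, ring.number_of_edges(), seed=seed)
            lattice_gammas.append(
                graph_metrics(nx.to_numpy_array(ring), seed=seed).gamma)
            if nx.number_of_edges(rnd):
                random_gammas.append(
                    graph_metrics(nx.to_numpy_array(rnd), seed=seed).gamma)
        assert np.mean(lattice_gammas) > np.mean(random_gammas)


class TestThresholdSweep:
    def test_grid_sizes(self):
        assert len(sweep_thresholds("coherence")) == 39
        assert len(sweep_thresholds("correlation")) == 39
        assert len(sweep_thresholds("plv")) == 39
        assert len(sweep_thresholds("pli")) == 199

    def test_edge_count_nonincreasing_and_low_T_complete(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.02, 0.98, size=(12, 12))
        vals = np.triu(vals, 1)
        vals = vals + vals.T
        np.fill_diagonal(vals, 1.0)
        counts = [binarize(vals, float(t)).n_edges
                  for t in sweep_thresholds("coherence")]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        g0 = binarize(vals, 0.01)
        _, c0 = clustering_coefficient(g0)
        assert c0 == pytest.approx(1.0)  # T -> 0+: complete graph
        assert characteristic_path_length(g0) == pytest.approx(1.0)

    def test_sweep_records_undefined_thresholds_as_missing(self):
        vals = np.full((6, 6), 0.3)
        np.fill_diagonal(vals, 0.0)
        m = ConnectivityMatrix(vals, "pli", BANDS["alpha"])
        sweep = threshold_sweep(m, n_random=3, seed=0)
        assert len(sweep) == 199
        defined = [gm for _, gm in sweep if gm is not None]
        missing = [T for T, gm in sweep if gm is None]
        assert defined and missing  # edges below 0.3 thresholds only
        assert all(T >= 0.3 for T in missing)


class TestGroupTTest:
    def test_identical_groups_no_flags(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.2, 0.4, size=(6, 10))
        out = group_node_ttest(a, a.copy())
        assert (out["p"] > 0.99).all()
        assert (out["flag"] == "").all()

    def test_shifted_node_flagged_with_direction(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.3, 0.01, size=(8, 5))
        b = a + 0.0
        b = b.copy()
        b[:, 2] += 0.5
        out = group_node_ttest(a, b)
        assert out.loc[2, "flag"] == "sig"
        assert out.loc[2, "direction"] == -1.0  # group A below group B

    def test_matches_closed_form_two_sample_t(self):
        # classical worked example: means 10 vs 12, sd 1, n 5 per group
        a = np.array([10.0, 11.0, 9.0, 10.0 + np.sqrt(2) / 2, 10.0 - np.sqrt(2) / 2])
        b = a + 2.0
        sa, sb = a.std(ddof=1), b.std(ddof=1)
        sp = np.sqrt((4 * sa**2 + 4 * sb**2) / 8)
        expected_t = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 5))
        out = group_node_ttest(a[:, None], b[:, None])
        assert out.loc[0, "t"] == pytest.approx(expected_t)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_node_ttest(np.ones((1, 4)), np.ones((5, 4)))

    def test_fdr_switch_monotone(self):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.8])
        q = fdr_correct(p)
        assert np.all(q >= p - 1e-12)
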