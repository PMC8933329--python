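"""Matrix construction, binarization and graph-metric oracle equivalence."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrconnectome.connectome import (
    ConnectivityMatrix,
    average_degree,
    binarize,
    count_connections,
    diff_metrics,
    global_efficiency,
    graph_metrics,
    group_edge_prevalence,
    local_efficiency,
    matrices_for_subject,
    submatrix,
)
from vrconnectome.regions import StimulationMap
from vrconnectome.tracking import FiberRecord


# --- definitional brute-force oracles -------------------------------------

def floyd_warshall(adjacency):
    n = adjacency.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adjacency > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def eg_oracle(adjacency):
    n = adjacency.shape[0]
    if n < 2:
        return 0.0
    dist = floyd_warshall(adjacency)
    total = sum(1.0 / dist[i, j]
                for i in range(n) for j in range(n)
                if i != j and np.isfinite(dist[i, j]))
    return total / (n * (n - 1))


def el_oracle(adjacency):
    n = adjacency.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adjacency[i])
        if len(nbrs) >= 2:
            total += eg_oracle(adjacency[np.ix_(nbrs, nbrs)])
    return total / n


def random_adjacency(rng, n, p):
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    adj = (adj | adj.T).astype(np.int8)
    return adj


# --- metric oracle equivalence ---------------------------------------------

class TestMetricOracles:
    def test_closed_forms(self):
        complete4 = 1 - np.eye(4, dtype=int)
        assert average_degree(complete4) == pytest.approx(3.0)
        assert global_efficiency(complete4) == pytest.approx(1.0)
        assert local_efficiency(complete4) == pytest.approx(1.0)

        star = np.zeros((5, 5), dtype=int)
        star[0, 1:] = star[1:, 0] = 1
        assert local_efficiency(star) == pytest.approx(0.0)

        path3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert global_efficiency(path3) == pytest.approx(5.0 / 6.0)

        triangle = 1 - np.eye(3, dtype=int)
        assert local_efficiency(triangle) == pytest.approx(1.0)

        empty = np.zeros((4, 4), dtype=int)
        assert average_degree(empty) == 0.0
        assert global_efficiency(empty) == 0.0

    def test_empty_and_single_node(self):
        assert average_degree(np.zeros((0, 0))) == 0.0
        assert global_efficiency(np.zeros((1, 1))) == 0.0
        assert local_efficiency(np.zeros((1, 1))) == 0.0

    def test_matches_brute_force_and_networkx(self, rng):
        """AD/EG/EL equal the definitional oracles (and networkx) to 1e-12 on
        random graphs up to 12 nodes."""
        for _ in range(200):
            n = int(rng.integers(2, 13))
            adj = random_adjacency(rng, n, float(rng.uniform(0.1, 0.9)))
            g = nx.from_numpy_array(adj)
            assert average_degree(adj) == pytest.approx(
                2 * g.number_of_edges() / n, abs=1e-12)
            assert global_efficiency(adj) == pytest.approx(eg_oracle(adj), abs=1e-12)
            assert local_efficiency(adj) == pytest.approx(el_oracle(adj), abs=1e-12)
            assert global_efficiency(adj) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12)
            assert local_efficiency(adj) == pytest.approx(
                nx.local_efficiency(g), abs=1e-12)

    @given(st.integers(0, 10**9))
    @settings(max_examples=60, deadline=None)
    def test_edge_addition_monotonicity(self, seed):
        """Adding edges never decreases AD or EG (EL is not monotone)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        adj = random_adjacency(rng, n, 0.4)
        zeros = np.argwhere((np.triu(np.ones((n, n)), 1) > 0) & (adj == 0))
        if len(zeros) == 0:
            return
        i, j = zeros[rng.integers(len(zeros))]
        bigger = adj.copy()
        bigger[i, j] = bigger[j, i] = 1
        assert average_degree(bigger) >= average_degree(adj)
        assert global_efficiency(bigger) >= global_efficiency(adj) - 1e-12

    def test_metrics_within_bounds(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 15))
            adj = random_adjacency(rng, n, float(rng.uniform(0, 1)))
            m = graph_metrics(adj)
            assert 0.0 <= m["eg"] <= 1.0
            assert 0.0 <= m["el"] <= 1.0
            assert 0.0 <= m["ad"] <= n - 1


# --- binarization and counting ---------------------------------------------

class TestBinarize:
    @pytest.mark.parametrize("count,expected", [(0, 0), (3, 0), (4, 1), (10, 1)])
    def test_more_than_three_boundary(self, count, expected):
        counts = np.array([[0, count], [count, 0]])
        assert binarize(counts)[0, 1] == expected

    def test_all_zero_counts_empty_graph(self):
        assert binarize(np.zeros((5, 5), dtype=int)).sum() == 0

    def test_configurable_min_count(self):
        counts = np.array([[0, 2], [2, 0]])
        assert binarize(counts, min_count=1)[0, 1] == 1


def _fiber_between(parcellation, region_a, region_b, n_points=12):
    from vrconnectome.synthetic import region_centroids

    cents = region_centroids(parcellation)
    t = np.linspace(0, 1, n_points)[:, None]
    pts = cents[region_a][None, :] * (1 - t) + cents[region_b][None, :] * t
    return FiberRecord(points=pts, fa=np.full(n_points, 0.5))


class TestCounting:
    def test_endpoint_counting(self, toy_parcellation):
        fibers = [_fiber_between(toy_parcellation, 1, 2) for _ in range(5)]
        counts, stats = count_connections(fibers, toy_parcellation)
        assert counts[0, 1] == counts[1, 0] == 5
        assert stats == {"used": 5, "dropped_unassigned": 0, "dropped_same_region": 0}

    def test_background_endpoint_dropped(self, toy_parcellation):
        fib = _fiber_between(toy_parcellation, 1, 2)
        fib.points[-1] = [-100.0, -100.0, -100.0]
        counts, stats = count_connections([fib], toy_parcellation)
        assert counts.sum() == 0
        assert stats["dropped_unassigned"] == 1

    def test_same_region_endpoints_dropped(self, toy_parcellation):
        fib = _fiber_between(toy_parcellation, 1, 2)
        fib.points[-1] = fib.points[0]
        counts, stats = count_connections([fib], toy_parcellation)
        assert counts.sum() == 0
        assert stats["dropped_same_region"] == 1

    def test_phantom_counts_match_ground_truth(self, small_cohort):
        """Endpoint counts reproduce the per-bundle fiber numbers the
        generator drew."""
        sid = small_cohort.records.subject_id.iloc[0]
        counts, stats = count_connections(small_cohort.fibers[sid],
                                          small_cohort.parcellation)
        node_ids = list(small_cohort.parcellation.node_ids)
        bundles = small_cohort.phantom.bundles
        kept = set(small_cohort.ground_truth[sid]["kept_bundles"])
        # every generated fiber lands with both endpoints in its bundle's regions
        assert stats["used"] == len(small_cohort.fibers[sid])
        # every counted pair corresponds to a kept ground-truth bundle
        wired = {(min(b.spec.region_a, b.spec.region_b),
                  max(b.spec.region_a, b.spec.region_b))
                 for j, b in enumerate(bundles) if j in kept}
        nz = np.argwhere(np.triu(counts, 1) > 0)
        for i, j in nz:
            assert (node_ids[i], node_ids[j]) in wired


class TestSubmatrix:
    def make_matrix(self, rng, node_ids):
        n = len(node_ids)
        counts = rng.integers(0, 8, size=(n, n))
        counts = counts + counts.T
        np.fill_diagonal(counts, 0)
        return ConnectivityMatrix(node_ids=np.asarray(node_ids), counts=counts,
                                  adjacency=binarize(counts), kind="whole",
                                  vr_threshold=25.0)

    def test_hemisphere_shapes(self, rng):
        m = self.make_matrix(rng, list(range(1, 91)))
        left = submatrix(m, range(1, 46))
        assert left.counts.shape == (45, 45)
        np.testing.assert_array_equal(left.node_ids, np.arange(1, 46))

    def test_identity_on_full_subset(self, rng):
        m = self.make_matrix(rng, [3, 5, 9])
        same = submatrix(m, [3, 5, 9])
        np.testing.assert_array_equal(same.counts, m.counts)

    def test_singleton_subset(self, rng):
        m = self.make_matrix(rng, [3, 5, 9])
        one = submatrix(m, [5])
        assert one.counts.shape == (1, 1) and one.counts[0, 0] == 0

    def test_unknown_id_raises(self, rng):
        m = self.make_matrix(rng, [3, 5, 9])
        with pytest.raises(KeyError):
            submatrix(m, [42])

    def test_induced_subgraph_drops_external_edges(self, rng):
        m = self.make_matrix(rng, [1, 2, 3, 4])
        sub = submatrix(m, [1, 4])
        assert sub.adjacency[0, 1] == m.adjacency[0, 3]


class TestDiffAndPrevalence:
    def test_paper_style_difference(self):
        assert diff_metrics({"ad": 7.635, "eg": 0, "el": 0},
                            {"ad": 2.863, "eg": 0, "el": 0})["ad_diff"] == pytest.approx(4.772)

    def test_identical_graphs_zero_diff(self):
        m = {"ad": 1.0, "eg": 0.4, "el": 0.2}
        assert all(v == 0 for v in diff_metrics(m, m).values())

    def test_nested_edge_sets_nonnegative_ad_eg_diff(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 12))
            big = random_adjacency(rng, n, 0.5)
            mask = np.triu(rng.random((n, n)) < 0.6, 1)
            small = (big & (mask | mask.T)).astype(np.int8)
            d = diff_metrics(graph_metrics(big), graph_metrics(small))
            assert d["ad_diff"] >= -1e-12
            assert d["eg_diff"] >= -1e-12

    def test_prevalence_counts_and_mask(self, rng):
        adjs = [random_adjacency(rng, 6, 0.5) for _ in range(30)]
        prevalence, masked = group_edge_prevalence(adjs, min_subjects=10)
        brute = sum(a > 0 for a in adjs)
        np.testing.assert_array_equal(prevalence, brute)
        assert (masked[(prevalence < 10)] == 0).all()
        assert (masked[(prevalence >= 10)] == prevalence[(prevalence >= 10)]).all()


class TestFiveMatrices:
    def test_per_subject_kinds_and_shapes(self, small_cohort, rng):
        parc = small_cohort.parcellation
        sid = small_cohort.records.subject_id.iloc[1]
        counts, _ = count_connections(small_cohort.fibers[sid], parc)
        stim = small_cohort.stim_maps[sid]
        mats = matrices_for_subject(counts, parc, stim, 25.0)
        assert mats["whole"].counts.shape == (parc.n_regions,) * 2
        assert mats["left"].counts.shape == (len(parc.left_ids),) * 2
        assert mats["right"].counts.shape == (len(parc.right_ids),) * 2
        assert mats["pos"].n_nodes == stim.n_pos
        assert mats["neg"].n_nodes == stim.n_neg
        for m in mats.values():
            np.testing.assert_array_equal(m.adjacency, m.adjacency.T)
            assert np.diagonal(m.adjacency).sum() == 0
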