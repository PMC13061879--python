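"""Crowding graph generators, spatial orderings, rewiring, and baselines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, chi2_contingency

from crowdnet import (
    CrowdingParams,
    DirectedGraph,
    OrderingPolicy,
    SpatialLayout,
    generate_crowding,
    generate_er_min1,
    generate_regular_indegree,
    indegree_pmf,
    rewire_shortcuts,
    ring_distance,
    torus_distance,
)
from crowdnet.metrics import _clustering_and_path


def _pooled_indegrees(params, policy, layout, n_graphs, rng):
    return np.concatenate(
        [
            generate_crowding(params, policy, layout, rng=rng).in_degrees()
            for _ in range(n_graphs)
        ]
    )


def _tv_to_pmf(degrees, pmf):
    emp = np.bincount(degrees, minlength=pmf.probs.size) / degrees.size
    return 0.5 * np.abs(emp - pmf.probs).sum()


class TestGenerateCrowding:
    def test_zero_alpha_gives_complete_digraph(self):
        g = generate_crowding(CrowdingParams(0.0, 50), seed=0)
        assert np.all(g.in_degrees() == 49)
        assert np.all(g.out_degrees() == 49)

    def test_uniform_order_matches_recursion(self, rng):
        params = CrowdingParams(0.77, 100)
        degs = _pooled_indegrees(params, OrderingPolicy(mode="uniform"), None, 150, rng)
        assert _tv_to_pmf(degs, indegree_pmf(params)) < 0.05

    def test_distance_order_matches_recursion(self, rng):
        params = CrowdingParams(1.5, 100)
        lay = SpatialLayout.ring(100)
        degs = _pooled_indegrees(params, OrderingPolicy(mode="distance"), lay, 150, rng)
        assert _tv_to_pmf(degs, indegree_pmf(params)) < 0.05

    def test_soft_order_matches_recursion(self, rng):
        params = CrowdingParams(1.5, 100)
        lay = SpatialLayout.ring(100)
        policy = OrderingPolicy(mode="soft", epsilon=0.1)
        degs = _pooled_indegrees(params, policy, lay, 100, rng)
        assert _tv_to_pmf(degs, indegree_pmf(params)) < 0.05

    def test_torus_order_matches_recursion(self, rng):
        params = CrowdingParams(1.5, 64)
        lay = SpatialLayout.torus(8)
        degs = _pooled_indegrees(params, OrderingPolicy(mode="distance"), lay, 150, rng)
        assert _tv_to_pmf(degs, indegree_pmf(params)) < 0.05

    def test_every_node_has_indegree_at_least_one(self, rng):
        g = generate_crowding(CrowdingParams(4.0, 200), rng=rng)
        assert g.in_degrees().min() >= 1

    @given(
        alpha=st.floats(min_value=0.0, max_value=5.0),
        n=st.integers(min_value=2, max_value=60),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_graph_validity_invariants(self, alpha, n, seed):
        g = generate_crowding(CrowdingParams(alpha, n), seed=seed)
        assert np.all(g.edges[:, 0] != g.edges[:, 1])
        assert np.unique(g.edges, axis=0).shape[0] == g.n_edges
        assert g.in_degrees().min() >= 1

    def test_missing_layout_rejected(self):
        with pytest.raises(ValueError):
            generate_crowding(
                CrowdingParams(1.0, 10), OrderingPolicy(mode="distance"), None, seed=0
            )


class TestDistances:
    def test_ring_distance_examples(self):
        lay = SpatialLayout.ring(10)
        assert ring_distance(lay, 0, 3) == 3
        assert ring_distance(lay, 0, 8) == 2
        assert ring_distance(lay, 0, 5) == 5

    def test_torus_distance_examples(self):
        lay = SpatialLayout.torus(10)
        assert torus_distance(lay, 0, 3) == pytest.approx(3.0)
        assert torus_distance(lay, 0, 9 * 10 + 9) == pytest.approx(math.sqrt(2))
        assert torus_distance(lay, 0, 5 * 10 + 5) == pytest.approx(math.sqrt(50))

    def test_self_distance_rejected(self):
        with pytest.raises(ValueError):
            ring_distance(SpatialLayout.ring(10), 4, 4)
        with pytest.raises(ValueError):
            torus_distance(SpatialLayout.torus(4), 3, 3)

    def test_torus_requires_square(self):
        with pytest.raises(ValueError):
            SpatialLayout(kind="torus", n_nodes=10, side=3)


class TestRewireShortcuts:
    def test_rho_zero_is_identity(self, rng):
        g = generate_crowding(CrowdingParams(2.0, 80), rng=rng)
        g2 = rewire_shortcuts(g, 0.0, seed=1)
        assert g2.edge_set() == g.edge_set()

    def test_indegree_vector_preserved_exactly(self, rng):
        lay = SpatialLayout.ring(500)
        g = generate_crowding(
            CrowdingParams(2.66, 500), OrderingPolicy(mode="distance"), lay, rng=rng
        )
        g2 = rewire_shortcuts(g, 0.5, seed=2)
        assert np.array_equal(g2.in_degrees(), g.in_degrees())
        assert np.all(g2.edges[:, 0] != g2.edges[:, 1])
        assert np.unique(g2.edges, axis=0).shape[0] == g2.n_edges

    def test_full_rewiring_reduces_clustering(self, rng):
        lay = SpatialLayout.ring(300)
        g = generate_crowding(
            CrowdingParams(2.66, 300), OrderingPolicy(mode="distance"), lay, rng=rng
        )
        g_rewired = rewire_shortcuts(g, 1.0, seed=3)
        c0 = _clustering_and_path(g)[0]
        c1 = _clustering_and_path(g_rewired)[0]
        assert c1 < c0

    def test_saturated_targets_are_skipped(self):
        g = generate_crowding(CrowdingParams(0.0, 6), seed=0)  # complete digraph
        g2 = rewire_shortcuts(g, 1.0, seed=1)
        assert g2.edge_set() == g.edge_set()
        assert g2.metadata["rewire_skipped"] == g.n_edges


class TestBaselines:
    def test_er_min1_mean_and_support(self, rng):
        degs = np.concatenate(
            [generate_er_min1(500, 3.0, rng=rng).in_degrees() for _ in range(40)]
        )
        assert degs.min() >= 1
        se = degs.std() / math.sqrt(degs.size)
        assert abs(degs.mean() - 3.0) < 3 * se

    def test_er_min1_dense_limit_complete(self):
        g = generate_er_min1(10, 9.0, seed=0)
        assert np.all(g.in_degrees() == 9)

    def test_er_min1_shape_differs_from_crowding(self, rng):
        # matched mean ~3 but different distribution shape
        from crowdnet import solve_alpha_for_mean

        alpha = solve_alpha_for_mean(500, 3.0)
        params = CrowdingParams(alpha, 500)
        c = np.concatenate(
            [generate_crowding(params, rng=rng).in_degrees() for _ in range(30)]
        )
        e = np.concatenate(
            [generate_er_min1(500, 3.0, rng=rng).in_degrees() for _ in range(30)]
        )
        kmax = max(c.max(), e.max())
        tab = np.vstack(
            [np.bincount(c, minlength=kmax + 1), np.bincount(e, minlength=kmax + 1)]
        )
        tab = tab[:, tab.sum(axis=0) >= 5]
        p = chi2_contingency(tab).pvalue
        assert p < 0.01

    def test_regular_indegree_exact(self):
        g = generate_regular_indegree(500, 3, seed=0)
        assert np.all(g.in_degrees() == 3)

    def test_regular_complete_when_k_max(self):
        g = generate_regular_indegree(5, 4, seed=0)
        assert np.all(g.in_degrees() == 4)
        assert np.all(g.out_degrees() == 4)

    def test_regular_outdegree_binomial(self, rng):
        outs = np.concatenate(
            [generate_regular_indegree(500, 3, rng=rng).out_degrees() for _ in range(100)]
        )
        emp = np.bincount(outs, minlength=500) / outs.size
        model = binom.pmf(np.arange(500), 499, 3 / 499)
        assert 0.5 * np.abs(emp - model).sum() < 0.05

    def test_er_min1_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            generate_er_min1(100, 0.2, seed=0)
        with pytest.raises(ValueError):
            generate_regular_indegree(100, 0, seed=0)


class TestDirectedGraphValidation:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            DirectedGraph(3, np.array([[0, 0]]))

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError):
            DirectedGraph(3, np.array([[0, 1], [0, 1]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            DirectedGraph(3, np.array([[0, 5]]))
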