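"""Static topology measures against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from oracles import (
    brute_assortativity,
    brute_betweenness,
    brute_closeness,
    brute_clustering,
    brute_eigenvector,
)
from ppintopo.fixtures import FixtureSpec, make_graph
from ppintopo.metrics import (
    annd,
    assortativity,
    betweenness,
    closeness,
    clustering,
    degree_distribution,
    eigenvector_centrality,
    hub_contribution,
    impact_curves,
    metric_vector,
)
from conftest import random_connected_net


class TestDegreeDistribution:
    def test_star_hub_and_leaves(self, star10):
        dist = degree_distribution(star10)
        assert dist.k_max == 10
        assert dist.counts[1] == 10
        assert dist.k_max_node == "n0000"

    def test_clique_is_regular(self, clique5):
        dist = degree_distribution(clique5)
        assert dist.counts == {4: 5}

    def test_probabilities_sum_to_one_and_handshake(self):
        net = random_connected_net(60, 0.08, 3)
        dist = degree_distribution(net)
        assert math.isclose(sum(dist.p_k.values()), 1.0, abs_tol=1e-12)
        assert sum(k * c for k, c in dist.counts.items()) == 2 * net.n_edges


class TestAssortativity:
    def test_star_is_perfectly_disassortative(self):
        for n in (2, 5, 20):
            net = make_graph(FixtureSpec.make("star", n=n))
            assert assortativity(net).r == pytest.approx(-1.0)

    def test_regular_graph_is_undefined(self):
        net = make_graph(FixtureSpec.make("cycle", n=6))
        stats = assortativity(net)
        assert stats.r is None and not stats.is_defined

    def test_mixing_matrix_is_symmetric_and_normalized(self):
        net = random_connected_net(40, 0.1, 1)
        stats = assortativity(net)
        assert math.isclose(sum(stats.e_xy.values()), 1.0, abs_tol=1e-12)
        for (x, y), w in stats.e_xy.items():
            assert stats.e_xy[(y, x)] == pytest.approx(w)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pearson_oracle_on_random_graphs(self, seed):
        net = random_connected_net(30, 0.12, seed)
        expected = brute_assortativity(net)
        observed = assortativity(net).r
        if expected is None:
            assert observed is None
        else:
            assert observed == pytest.approx(expected, abs=1e-10)


class TestAnnd:
    def test_star_leaves_see_hub_degree(self, star10):
        result = annd(star10)
        assert result.vector.values["n0000"] == pytest.approx(1.0)  # hub sees leaves
        assert result.vector.values["n0001"] == pytest.approx(10.0)

    def test_clique_neighbors_all_same_degree(self):
        net = make_graph(FixtureSpec.make("clique", n=4))
        assert set(annd(net).vector.values.values()) == {3.0}

    def test_matches_adjacency_row_oracle(self):
        net = make_graph(FixtureSpec.make("erdos_renyi", n=200, p=0.05, seed=11))
        from ppintopo.network import largest_component

        net = largest_component(net)
        deg = net.degrees()
        result = annd(net)
        for node in net.nodes:
            expected = np.mean([deg[w] for w in net.graph.neighbors(node)])
            assert result.vector.values[node] == pytest.approx(expected)

    def test_normalization_divides_both_axes_by_n(self, star10):
        raw = annd(star10, normalized=False)
        norm = annd(star10, normalized=True)
        n = star10.n_nodes
        assert norm.plot_table["k"].tolist() == pytest.approx(
            [k / n for k in raw.plot_table["k"]]
        )
        assert norm.vector.values["n0001"] == pytest.approx(10.0 / n)


class TestImpactCurves:
    def test_star_has_no_leaf_leaf_edges(self):
        net = make_graph(FixtureSpec.make("star", n=10))
        curve = impact_curves(net)
        assert curve.s1[0] == 0.0
        assert curve.m[0] == pytest.approx(10 / 11)
        assert curve.s1[-1] == 1.0 and curve.m[-1] == 1.0

    def test_clique_jumps_at_its_single_degree(self):
        net = make_graph(FixtureSpec.make("clique", n=6))
        curve = impact_curves(net)
        assert np.all(curve.s1[:-1] == 0.0)
        assert curve.s1[-1] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_with_unit_endpoints(self, seed):
        net = random_connected_net(50, 0.08, seed)
        curve = impact_curves(net)
        assert np.all(np.diff(curve.s1) >= 0)
        assert np.all(np.diff(curve.m) >= 0)
        assert curve.s1[-1] == 1.0 and curve.m[-1] == 1.0

    def test_subnetwork_counts_match_explicit_construction(self):
        net = random_connected_net(40, 0.1, 9)
        deg = net.degrees()
        curve = impact_curves(net)
        for i, cutoff in enumerate(curve.k):
            kept = {v for v, k in deg.items() if k <= cutoff}
            edges = sum(1 for u, v in net.graph.edges if u in kept and v in kept)
            assert curve.s1[i] == pytest.approx(edges / net.n_edges)
            assert curve.m[i] == pytest.approx(len(kept) / net.n_nodes)


class TestHubContribution:
    def test_star_hub_touches_everything(self, star10):
        assert hub_contribution(star10, 1) == 1.0

    def test_clique_single_node_share(self, clique5):
        assert hub_contribution(clique5, 1) == pytest.approx(0.4)

    def test_top_n_larger_than_network_rejected(self, clique5):
        with pytest.raises(ValueError):
            hub_contribution(clique5, 6)


class TestBetweenness:
    def test_path3_middle_carries_the_single_pair(self, path3):
        vec = betweenness(path3)
        assert vec.max_value == pytest.approx(1.0)
        assert vec.values["n0000"] == 0.0 and vec.values["n0002"] == 0.0

    def test_path4_inner_nodes(self):
        net = make_graph(FixtureSpec.make("path", n=4))
        vec = betweenness(net)
        assert vec.values["n0001"] == pytest.approx(2 / 3)
        assert vec.values["n0002"] == pytest.approx(2 / 3)

    def test_tiny_network_all_zero(self):
        net = make_graph(FixtureSpec.make("path", n=2))
        assert set(betweenness(net).values.values()) == {0.0}


class TestCloseness:
    def test_star_hub_and_leaf(self):
        net = make_graph(FixtureSpec.make("star", n=3))
        vec = closeness(net)
        assert vec.values["n0000"] == pytest.approx(1.0)
        assert vec.values["n0001"] == pytest.approx(0.6)  # (n-1)/(1+2(n-1)), n=4 nodes

    def test_clique_all_ones(self, clique5):
        assert set(closeness(clique5).values.values()) == {1.0}

    def test_disconnected_input_rejected(self):
        from ppintopo.network import build_network

        net, _ = build_network([("A", "B"), ("X", "Y")])
        with pytest.raises(ValueError):
            closeness(net)


class TestEigenvector:
    def test_star_closed_form(self):
        n = 9
        net = make_graph(FixtureSpec.make("star", n=n))
        vec = eigenvector_centrality(net)
        assert vec.values["n0000"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert vec.values["n0001"] == pytest.approx(1 / math.sqrt(2 * n), abs=1e-8)

    def test_clique_uniform(self, clique5):
        vec = eigenvector_centrality(clique5)
        assert list(vec.values.values()) == pytest.approx([1 / math.sqrt(5)] * 5)

    def test_unit_euclidean_norm(self):
        net = random_connected_net(40, 0.1, 5)
        vec = eigenvector_centrality(net)
        assert np.linalg.norm(list(vec.values.values())) == pytest.approx(1.0)

    def test_nonconvergence_carries_last_iterate(self, clique5):
        from ppintopo.metrics import PowerIterationError

        with pytest.raises(PowerIterationError) as exc_info:
            eigenvector_centrality(clique5, tol=0.0, max_iter=3)
        assert set(exc_info.value.last_iterate) == clique5.nodes


class TestClustering:
    def test_triangle_fully_clustered(self):
        net = make_graph(FixtureSpec.make("cycle", n=3))
        assert set(clustering(net).values.values()) == {1.0}

    def test_star_has_no_neighbor_links(self, star10):
        vec = clustering(star10)
        assert set(vec.values.values()) == {0.0}
        assert vec.mean == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_centralities_match_brute_force_on_random_graphs(seed):
    """Exact agreement with handwritten oracles on small random networks."""
    net = random_connected_net(28, 0.15, seed)
    for func, oracle, tol in [
        (betweenness, brute_betweenness, 1e-10),
        (closeness, brute_closeness, 1e-10),
        (clustering, brute_clustering, 1e-12),
        (lambda g: eigenvector_centrality(g, tol=1e-13), brute_eigenvector, 1e-8),
    ]:
        ours = func(net).values
        expected = oracle(net)
        for node in net.nodes:
            assert ours[node] == pytest.approx(expected[node], abs=tol), func


def test_metric_vector_dispatch_and_unknown_name(star10):
    assert metric_vector(star10, "degree").values["n0000"] == 10.0
    with pytest.raises(ValueError):
        metric_vector(star10, "pagerank")
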