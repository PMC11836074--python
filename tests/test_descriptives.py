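"""Component decomposition and descriptive network/word measures."""

import math

import networkx as nx
import numpy as np
import pytest

from phononet import (
    DegenerateGraphError,
    assortativity,
    average_clustering,
    closeness_centrality,
    clustering_coefficient,
    compare_groups,
    decompose,
    degree_stats,
    density,
    heterogeneity,
    network_summary,
)
from phononet.descriptives import aspl_and_diameter, closeness_all, word_measures


@pytest.fixture(scope="module")
def toy6():
    """6-node graph with mixed degrees for hand-checked formula evaluation."""
    return nx.Graph([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f")])


class TestDecompose:
    def test_toy8(self, toy8):
        c = decompose(toy8)
        assert (c.giant_nodes, c.island_nodes, c.hermit_nodes) == (3, 2, 3)
        assert c.island_count == 1
        assert c.giant_pct == pytest.approx(37.5)
        assert c.giant_pct + c.island_pct + c.hermit_pct == pytest.approx(100.0)

    def test_edgeless_graph_all_hermits(self):
        g = nx.empty_graph(5)
        c = decompose(g)
        assert c.giant_nodes == 0 and c.hermit_nodes == 5 and c.island_count == 0

    def test_partition_is_exact(self, medium_net):
        c = decompose(medium_net)
        assert c.giant_nodes + c.island_nodes + c.hermit_nodes == c.n


class TestDensity:
    def test_two_node_edge(self):
        assert density(2, 1) == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            density(1, 0)

    def test_matches_networkx(self, toy8):
        assert density(toy8.number_of_nodes(), toy8.number_of_edges()) == pytest.approx(
            nx.density(toy8)
        )


class TestDegreeStats:
    def test_mean_identity(self, toy6):
        mean, mx, sd = degree_stats(toy6, "whole")
        assert mean == pytest.approx(2 * toy6.number_of_edges() / toy6.number_of_nodes())
        assert mx == 3

    def test_single_isolated_node(self):
        g = nx.Graph()
        g.add_node("a")
        assert degree_stats(g, "whole") == (0.0, 0, 0.0)

    def test_giant_scope(self, toy8):
        mean, mx, sd = degree_stats(toy8, "giant")
        assert mean == pytest.approx(2.0)  # triangle
        assert sd == 0.0


class TestAssortativity:
    def test_star_is_minus_one(self):
        assert assortativity(nx.star_graph(5)) == pytest.approx(-1.0)

    def test_uniform_degree_undefined(self):
        with pytest.raises(DegenerateGraphError):
            assortativity(nx.cycle_graph(4))

    def test_toy_matches_direct_pearson(self, toy6):
        deg = dict(toy6.degree())
        pairs = [(deg[u], deg[v]) for u, v in toy6.edges]
        xs = [a for a, b in pairs] + [b for a, b in pairs]
        ys = [b for a, b in pairs] + [a for a, b in pairs]
        expected = np.corrcoef(xs, ys)[0, 1]
        assert assortativity(toy6) == pytest.approx(expected)

    def test_matches_networkx(self, small_net):
        assert assortativity(small_net) == pytest.approx(
            nx.degree_assortativity_coefficient(small_net), abs=1e-10
        )

    def test_within_bounds(self, medium_net):
        assert -1.0 <= assortativity(medium_net) <= 1.0


class TestHeterogeneity:
    def test_regular_graph_is_zero(self):
        assert heterogeneity(nx.cycle_graph(6)) == 0.0

    def test_star_is_one(self):
        for n in (4, 9, 25):
            assert heterogeneity(nx.star_graph(n - 1)) == pytest.approx(1.0)

    def test_toy_matches_term_sum(self, toy6):
        deg = dict(toy6.degree())
        raw = sum((deg[u] ** -0.5 - deg[v] ** -0.5) ** 2 for u, v in toy6.edges)
        n = toy6.number_of_nodes()
        assert heterogeneity(toy6) == pytest.approx(raw / (n - 2 * math.sqrt(n - 1)))

    def test_in_unit_interval(self, small_net):
        assert 0.0 <= heterogeneity(small_net) <= 1.0


class TestClustering:
    def test_triangle_node(self):
        assert clustering_coefficient(nx.complete_graph(3), 0) == 1.0

    def test_path_center(self):
        assert clustering_coefficient(nx.path_graph(3), 1) == 0.0

    def test_degree_lt_2_is_zero(self, toy8):
        assert clustering_coefficient(toy8, "d") == 0.0
        assert clustering_coefficient(toy8, "x") == 0.0

    def test_average_matches_hand_count(self, toy6):
        # a,b,c form a triangle; c has deg 3 with 1 of 3 pairs closed; d,e,f open
        expected = (1 + 1 + 1 / 3 + 0 + 0 + 0) / 6
        assert average_clustering(toy6) == pytest.approx(expected)


class TestCloseness:
    def test_path_center(self):
        assert closeness_centrality(nx.path_graph(3), 1) == 1.0

    def test_isolate_is_zero(self, toy8):
        assert closeness_centrality(toy8, "x") == 0.0

    def test_island_node_component_scaled(self, toy8):
        # 2-node island in an 8-node graph: (1/1) * (1/7)
        assert closeness_centrality(toy8, "d") == pytest.approx(1 / 7)

    def test_bulk_matches_per_node(self, toy8, small_net):
        for g in (toy8, small_net):
            bulk = closeness_all(g)
            nodes = list(g.nodes)[:50]
            for v in nodes:
                assert bulk[v] == pytest.approx(closeness_centrality(g, v), abs=1e-12)


class TestASPL:
    def test_path3(self):
        aspl, diam = aspl_and_diameter(nx.path_graph(3))
        assert aspl == pytest.approx(4 / 3) and diam == 2

    def test_matches_networkx(self, toy6):
        assert aspl_and_diameter(toy6)[0] == pytest.approx(
            nx.average_shortest_path_length(toy6)
        )

    def test_disconnected_rejected(self, toy8):
        with pytest.raises(ValueError):
            aspl_and_diameter(toy8)


class TestCompareGroups:
    def test_textbook_welch(self):
        r = compare_groups([1, 2, 3], [4, 5, 6])
        # hand evaluation: means 2, 5; s^2 = 1 each, n = 3
        t = (2 - 5) / math.sqrt(1 / 3 + 1 / 3)
        assert r.statistic == pytest.approx(t)
        assert r.dof == pytest.approx(4.0)
        assert r.direction == -1

    def test_zero_variance_equal_means_undefined(self):
        with pytest.raises(ValueError):
            compare_groups([2, 2, 2], [2, 2])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1], [2, 3])


class TestSummaries:
    def test_network_summary_identities(self, small_net):
        s = network_summary(small_net)
        assert s.density == pytest.approx(2 * s.e / (s.n * (s.n - 1)))
        gc_nodes = s.components.giant_nodes
        assert s.degree_mean > 0 and gc_nodes > 0

    def test_word_measures_shape(self, tiny_net):
        df = word_measures(tiny_net)
        assert set(df.columns) == {"degree", "clustering", "closeness", "length",
                                   "log10_frequency"}
        assert df.loc["cat", "degree"] == tiny_net.degree("cat")
        assert df.loc["sprint", "closeness"] == 0.0
        assert df.loc["cat", "length"] == 3
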