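import random

import pytest

from minkit.errors import (
    InvalidParameterError,
    UnknownInteractorError,
    WrongModeError,
)
from minkit.model import Interaction, build_graph
from minkit.neighborhood import (
    x_neighbors,
    x_subgraph,
    x_weighted_neighbors,
    x_weighted_subgraph,
)
from minkit.synth import oracle_khop, oracle_max_product

from conftest import random_graph


class TestXNeighbors:
    def test_one_hop(self, g1):
        result = x_neighbors(g1, {"a"}, 1)
        assert result.members == {"b", "c"}
        assert result.best_value == {"b": 1, "c": 1}

    def test_two_hops(self, g1):
        assert x_neighbors(g1, {"a"}, 2).members == {"b", "c", "d"}

    def test_reachability_bound(self, g2):
        assert x_neighbors(g2, {"a"}, 5).members == {"b"}

    def test_sources_excluded(self, g1):
        result = x_neighbors(g1, {"a", "b"}, 2)
        assert result.members.isdisjoint({"a", "b"})

    def test_validation(self, g1):
        with pytest.raises(InvalidParameterError):
            x_neighbors(g1, {"a"}, 0)
        with pytest.raises(UnknownInteractorError, match="nope"):
            x_neighbors(g1, {"nope"}, 1)

    def test_equals_bfs_oracle(self):
        for seed in range(100):
            rng = random.Random(seed)
            g = random_graph(rng, rng.randint(2, 25), p=0.2, weighted=False)
            sources = set(rng.sample(g.vertex_ids(), rng.randint(1, min(3, g.n_vertices))))
            for x in (1, 2, 3):
                expected = oracle_khop(g, sources, x)
                result = x_neighbors(g, sources, x)
                assert result.members == set(expected)
                assert result.best_value == expected


class TestXSubgraph:
    def test_one_hop_induced(self, g1):
        sub = x_subgraph(g1, {"a"}, 1)
        assert sorted(sub.vertex_ids()) == ["a", "b", "c"]
        assert {k for k, _ in sub.edge_items()} == {
            ("a", "b"), ("a", "c"), ("b", "c")}

    def test_full_source_set_identity(self, g1):
        assert x_subgraph(g1, set(g1.vertex_ids()), 3) == g1

    def test_from_leaf(self, g1):
        sub = x_subgraph(g1, {"d"}, 1)
        assert sorted(sub.vertex_ids()) == ["c", "d"]
        assert sub.n_edges == 1


class TestXWeightedNeighbors:
    def test_fixture_threshold_06(self, g1):
        result = x_weighted_neighbors(g1, "a", 0.6)
        assert result.members == {"b", "c"}
        assert result.best_value["b"] == pytest.approx(0.9)
        assert result.best_value["c"] == pytest.approx(0.72)

    def test_high_threshold_empty(self, g1):
        assert x_weighted_neighbors(g1, "a", 0.95).members == set()

    def test_all_ones_reaches_whole_component(self):
        g = build_graph([Interaction("a", "b", 1.0), Interaction("b", "c", 1.0),
                         Interaction("x", "y", 1.0)])
        assert x_weighted_neighbors(g, "a", 0.5).members == {"b", "c"}

    def test_strict_threshold(self):
        g = build_graph([Interaction("a", "b", 0.6)])
        assert x_weighted_neighbors(g, "a", 0.6).members == set()

    def test_mode_and_parameter_validation(self, g1, g2):
        with pytest.raises(WrongModeError):
            x_weighted_neighbors(g2, "a", 0.5)
        with pytest.raises(InvalidParameterError):
            x_weighted_neighbors(g1, "a", 1.5)
        with pytest.raises(UnknownInteractorError):
            x_weighted_neighbors(g1, "nope", 0.5)

    def test_direct_neighbor_best_at_least_edge_weight(self):
        for seed in range(50):
            rng = random.Random(seed)
            g = random_graph(rng, 10, p=0.4)
            source = g.vertex_ids()[0]
            result = x_weighted_neighbors(g, source, 0.1)
            for neighbor in g.neighbors(source):
                w = g.weight(source, neighbor)
                if w > 0.1:
                    assert result.best_value[neighbor] >= w - 1e-12

    def test_equals_path_enumeration_oracle(self):
        for seed in range(100):
            rng = random.Random(seed)
            g = random_graph(rng, rng.randint(2, 12), p=0.35)
            source = rng.choice(g.vertex_ids())
            oracle = oracle_max_product(g, source)
            for x in (0.1, 0.3, 0.5, 0.7, 0.9):
                result = x_weighted_neighbors(g, source, x)
                expected = {v: p for v, p in oracle.items() if p > x}
                assert result.members == set(expected)
                for v, p in expected.items():
                    assert result.best_value[v] == pytest.approx(p)


class TestXWeightedSubgraph:
    def test_fixture(self, g1):
        sub = x_weighted_subgraph(g1, "a", 0.6)
        assert sorted(sub.vertex_ids()) == ["a", "b", "c"]

    def test_empty_neighborhood_single_vertex(self, g1):
        sub = x_weighted_subgraph(g1, "a", 0.95)
        assert sub.vertex_ids() == ["a"]
        assert sub.n_edges == 0

    def test_all_ones_component(self):
        g = build_graph([Interaction("a", "b", 1.0), Interaction("b", "c", 1.0)])
        assert x_weighted_subgraph(g, "a", 0.5) == g


class TestMonotonicity:
    def test_weighted_neighborhood_shrinks_as_x_grows(self):
        for seed in range(60):
            rng = random.Random(seed)
            g = random_graph(rng, 12, p=0.3)
            source = rng.choice(g.vertex_ids())
            previous = None
            for x in (0.2, 0.4, 0.6, 0.8):
                members = x_weighted_neighbors(g, source, x).members
                if previous is not None:
                    assert members <= previous
                previous = members

    def test_unweighted_neighborhood_grows_with_hops(self):
        for seed in range(60):
            rng = random.Random(seed)
            g = random_graph(rng, 15, p=0.2, weighted=False)
            source = rng.choice(g.vertex_ids())
            previous = set()
            for x in (1, 2, 3, 4):
                members = x_neighbors(g, {source}, x).members
                assert previous <= members
                previous = members


def test_partition_invariance(g1):
    from minkit.model import Interaction, build_graph
    edges = [Interaction(a, b, w) for (a, b), w in g1.edge_items()]
    baseline = None
    for partitions in (1, 2, 7):
        g = build_graph(edges, partitions=partitions)
        result = x_weighted_neighbors(g, "a", 0.6,
                                      executor="parallel", workers=2)
        snapshot = (result.members, result.best_value)
        if baseline is None:
            baseline = snapshot
        assert snapshot == baseline
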