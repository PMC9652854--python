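import io as stdio
import random

import pytest

from minkit.errors import UndefinedStatisticError, UnknownInteractorError
from minkit.model import Interaction, Interactor, build_graph
from minkit.stats import (
    closeness,
    count_interactions,
    count_interactors,
    degrees,
    density,
    list_interactions,
    list_interactors,
    top_k_by_degree,
)

from conftest import random_graph


def complete_graph(n):
    ids = [f"k{i}" for i in range(n)]
    return build_graph([Interaction(a, b)
                        for i, a in enumerate(ids) for b in ids[i + 1:]])


def star_graph(n):
    return build_graph([Interaction("hub", f"leaf{i}") for i in range(n - 1)])


def path_graph(ids):
    return build_graph([Interaction(a, b) for a, b in zip(ids, ids[1:])])


def test_counts(g1):
    assert count_interactors(g1) == 4
    assert count_interactions(g1) == 4
    isolated = build_graph([], vertices=[Interactor(v) for v in "xyz"])
    assert count_interactors(isolated) == 3
    assert count_interactions(isolated) == 0
    assert count_interactions(complete_graph(5)) == 10


def test_list_interactors(g1):
    sink = stdio.StringIO()
    assert list_interactors(g1, sink) == 4
    assert sink.getvalue() == "a\nb\nc\nd\n"


def test_list_interactions_delegates_to_edge_list(g1):
    sink = stdio.StringIO()
    assert list_interactions(g1, sink) == 4
    assert sink.getvalue().splitlines()[0] == "a\tb\t0.9"


class TestDensity:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_is_one(self, n):
        assert density(complete_graph(n)) == 1.0

    def test_fixture_value(self, g1):
        assert density(g1) == pytest.approx(2 * 4 / (4 * 3))

    def test_edgeless(self):
        g = build_graph([], vertices=[Interactor(f"v{i}") for i in range(10)])
        assert density(g) == 0.0

    def test_undefined_below_two_vertices(self):
        g = build_graph([], vertices=[Interactor("a")])
        with pytest.raises(UndefinedStatisticError):
            density(g)


class TestDegrees:
    def test_fixture_ordering(self, g1):
        assert degrees(g1).rows == [("c", 3), ("a", 2), ("b", 2), ("d", 1)]

    def test_star(self):
        rows = degrees(star_graph(5)).rows
        assert rows[0] == ("hub", 4)
        assert all(d == 1 for _, d in rows[1:])

    def test_against_recount_oracle(self):
        g = random_graph(random.Random(3), 300, p=0.02)
        table = dict(degrees(g).rows)
        for v in g.vertex_ids():
            recount = sum(1 for key, _ in g.edge_items() if v in key)
            assert table[v] == recount

    def test_degree_sum_is_twice_edges(self):
        for seed in range(50):
            g = random_graph(random.Random(seed), 20)
            assert sum(d for _, d in degrees(g).rows) == 2 * g.n_edges


class TestTopK:
    def test_k1(self, g1):
        assert top_k_by_degree(g1, 1) == [("c", 3)]

    def test_tie_break_by_id_and_cutoff(self, g1):
        assert top_k_by_degree(g1, 2) == [("c", 3), ("a", 2)]

    def test_k_exceeding_vertex_count(self, g1):
        assert len(top_k_by_degree(g1, 10)) == 4


class TestCloseness:
    def test_star_center_attains_bound(self):
        g = star_graph(5)
        assert closeness(g, "hub") == 4.0

    def test_path(self):
        g = path_graph(["a", "b", "c"])
        assert closeness(g, "a") == 1.5

    def test_disconnected_contributes_zero(self, g2):
        assert closeness(g2, "a") == 1.0

    def test_unknown_node(self, g1):
        with pytest.raises(UnknownInteractorError, match="zzz"):
            closeness(g1, "zzz")

    def test_upper_bound(self):
        for seed in range(30):
            g = random_graph(random.Random(seed), 15)
            for v in g.vertex_ids():
                value = closeness(g, v)
                assert value <= g.n_vertices - 1 + 1e-12
                if g.degree(v) == g.n_vertices - 1:
                    assert value == pytest.approx(g.n_vertices - 1)

    def test_engine_agrees_with_bfs_oracle(self):
        from minkit.synth import oracle_khop
        for seed in range(200):
            g = random_graph(random.Random(seed), random.Random(seed).randint(2, 30), p=0.15)
            for v in list(g.vertex_ids())[:3]:
                oracle = sum(1.0 / d for d in
                             oracle_khop(g, {v}, g.n_vertices).values())
                assert closeness(g, v) == pytest.approx(oracle)
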