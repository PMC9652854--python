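"""Whole-network and per-interactor summary statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

from . import io as _io
from .engine import INF, hop_distance_program, run_supersteps
from .errors import UndefinedStatisticError
from .model import MINGraph


@dataclass
class DegreeTable:
    """Rows of (interactor id, degree), degree descending then id ascending."""

    rows: list[tuple[str, int]]

    def top(self, k: int) -> list[tuple[str, int]]:
        return self.rows[:k]


def count_interactors(g: MINGraph) -> int:
    """Number of interactors (|V|)."""
    return g.n_vertices


def count_interactions(g: MINGraph) -> int:
    """Number of interactions (|E|)."""
    return g.n_edges


def list_interactors(g: MINGraph, sink: TextIO) -> int:
    """Write one interactor id per line, lexicographically sorted."""
    ids = sorted(g.vertex_ids())
    for identifier in ids:
        sink.write(identifier + "\n")
    return len(ids)


def list_interactions(g: MINGraph, sink: TextIO) -> int:
    """Write the edge list (delegates to the io module's writer)."""
    return _io.write_edge_list(g, sink)


def density(g: MINGraph) -> float:
    """Graph density 2|E| / (|V| (|V| - 1)); undefined for |V| < 2."""
    n = g.n_vertices
    if n < 2:
        raise UndefinedStatisticError(f"density undefined for |V| = {n}")
    return 2.0 * g.n_edges / (n * (n - 1))


def degrees(g: MINGraph) -> DegreeTable:
    """Degree of every vertex, isolated vertices included with degree 0."""
    rows = [(v, len(g.adjacency[v])) for v in g.vertex_ids()]
    rows.sort(key=lambda row: (-row[1], row[0]))
    return DegreeTable(rows)


def top_k_by_degree(g: MINGraph, k: int) -> list[tuple[str, int]]:
    """First ``k`` rows of the degree table; ties broken by ascending id,
    rows beyond ``k`` left out even when tied with the k-th."""
    return degrees(g).top(k)


def closeness(
    g: MINGraph,
    p: str,
    executor: str = "serial",
    workers: int = 1,
) -> float:
    """Harmonic closeness of ``p``: sum over y != p of 1 / d(y, p).

    Distances are unweighted hop counts computed with the engine's
    breadth-first program; unreachable vertices contribute 0.
    """
    g.interactor(p)  # raises UnknownInteractorError
    result = run_supersteps(
        g, hop_distance_program({p}), executor=executor, workers=workers
    )
    total = 0.0
    for v, d in result.states.items():
        if v != p and d != INF and d > 0:
            total += 1.0 / d
    return total
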