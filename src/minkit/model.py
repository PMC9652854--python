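"""Core graph data types: interactors, interactions and the MIN graph.

A molecular interaction network (MIN) is an undirected simple graph whose
vertices are cellular components identified by free-text ids (canonically
``"db:accession"``, e.g. ``"uniprotkb:P04637"``) and whose edges may carry a
confidence label in [0, 1].  A graph is either fully *labelled* (every edge
has a weight) or fully unlabelled; mixed graphs are rejected at build time.

Edges are hashed into a fixed number of partitions so that downstream
vertex-centric computation can be split across workers; the partitioning is
stable across runs and never observable in results.
"""

from __future__ import annotations

import logging
import zlib
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import InvalidInputError, UnknownInteractorError

logger = logging.getLogger(__name__)

EdgeKey = tuple[str, str]


def canonical_pair(a: str, b: str) -> EdgeKey:
    """Return the unordered endpoint pair in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


def _check_id(identifier: str) -> None:
    if not identifier:
        raise InvalidInputError("interactor id must be non-empty")
    if "\t" in identifier or "\n" in identifier:
        raise InvalidInputError(
            f"interactor id contains tab/newline: {identifier!r}"
        )


@dataclass(frozen=True)
class Interactor:
    """A vertex of a MIN: a unique text id plus optional annotations."""

    id: str
    attributes: Mapping[str, str] = field(
        default_factory=dict, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        _check_id(self.id)


@dataclass(frozen=True)
class Interaction:
    """An undirected edge with an optional confidence weight in [0, 1].

    Endpoints are stored canonically (``endpoint_a <= endpoint_b``); the
    constructor reorders them, so ``Interaction("b", "a")`` equals
    ``Interaction("a", "b")``.
    """

    endpoint_a: str
    endpoint_b: str
    weight: float | None = None

    def __post_init__(self) -> None:
        _check_id(self.endpoint_a)
        _check_id(self.endpoint_b)
        if self.endpoint_a > self.endpoint_b:
            a, b = self.endpoint_b, self.endpoint_a
            object.__setattr__(self, "endpoint_a", a)
            object.__setattr__(self, "endpoint_b", b)
        if self.weight is not None:
            w = float(self.weight)
            if not (0.0 <= w <= 1.0):
                raise InvalidInputError(
                    f"weight {w} outside [0, 1] on edge "
                    f"({self.endpoint_a}, {self.endpoint_b})"
                )
            object.__setattr__(self, "weight", w)

    @property
    def key(self) -> EdgeKey:
        return (self.endpoint_a, self.endpoint_b)


class MINGraph:
    """Partitioned, undirected, optionally labelled interaction graph.

    Invariants (enforced by :func:`build_graph`):

    * every edge endpoint is a vertex;
    * no parallel edges, no self-loops;
    * either all edges carry a weight (``labelled``) or none do;
    * each edge belongs to exactly one of ``partitions`` partitions,
      assigned by a stable hash of the canonical endpoint pair.
    """

    def __init__(
        self,
        vertices: Mapping[str, Interactor],
        edges: Mapping[EdgeKey, float | None],
        labelled: bool,
        partitions: int = 1,
    ):
        self._vertices: dict[str, Interactor] = dict(vertices)
        self._edges: dict[EdgeKey, float | None] = dict(edges)
        self.labelled = labelled
        self.partitions = int(partitions)
        self._adjacency: dict[str, dict[str, float | None]] | None = None

    # -- basic accessors ---------------------------------------------------

    def vertex_ids(self) -> list[str]:
        return list(self._vertices)

    def interactor(self, identifier: str) -> Interactor:
        try:
            return self._vertices[identifier]
        except KeyError:
            raise UnknownInteractorError(identifier) from None

    def has_vertex(self, identifier: str) -> bool:
        return identifier in self._vertices

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge_items(self) -> Iterable[tuple[EdgeKey, float | None]]:
        return self._edges.items()

    def edges(self) -> list[Interaction]:
        return [Interaction(a, b, w) for (a, b), w in self._edges.items()]

    def weight(self, a: str, b: str) -> float | None:
        return self._edges[canonical_pair(a, b)]

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self._edges

    # -- adjacency ---------------------------------------------------------

    @property
    def adjacency(self) -> dict[str, dict[str, float | None]]:
        """Vertex id -> {neighbor id -> edge weight}; built lazily, cached."""
        if self._adjacency is None:
            adj: dict[str, dict[str, float | None]] = {
                v: {} for v in self._vertices
            }
            for (a, b), w in self._edges.items():
                adj[a][b] = w
                adj[b][a] = w
            self._adjacency = adj
        return self._adjacency

    def neighbors(self, identifier: str) -> set[str]:
        if identifier not in self._vertices:
            raise UnknownInteractorError(identifier)
        return set(self.adjacency[identifier])

    def degree(self, identifier: str) -> int:
        if identifier not in self._vertices:
            raise UnknownInteractorError(identifier)
        return len(self.adjacency[identifier])

    # -- partitioning ------------------------------------------------------

    def partition_of(self, key: EdgeKey) -> int:
        a, b = key
        return zlib.crc32(f"{a}\t{b}".encode("utf-8")) % self.partitions

    def edges_by_partition(self) -> list[list[EdgeKey]]:
        groups: list[list[EdgeKey]] = [[] for _ in range(self.partitions)]
        for key in self._edges:
            groups[self.partition_of(key)].append(key)
        return groups

    # -- equality ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MINGraph):
            return NotImplemented
        return (
            set(self._vertices) == set(other._vertices)
            and self._edges == other._edges
            and self.labelled == other.labelled
        )

    def __hash__(self) -> int:  # pragma: no cover - not used as dict key
        return hash((frozenset(self._vertices), frozenset(self._edges.items())))

    def __repr__(self) -> str:
        kind = "labelled" if self.labelled else "unlabelled"
        return (
            f"MINGraph({self.n_vertices} vertices, {self.n_edges} edges, "
            f"{kind}, {self.partitions} partition(s))"
        )


def build_graph(
    edges: Iterable[Interaction],
    vertices: Iterable[Interactor] | None = None,
    partitions: int = 1,
) -> MINGraph:
    """Build a validated :class:`MINGraph` from raw interaction records.

    Normalisation policy:

    * duplicate unordered pairs collapse to a single edge keeping the
      **maximum** weight;
    * self-loops are dropped (a warning with the count is logged);
    * explicitly supplied ``vertices`` are kept even when isolated;
    * a mixture of weighted and unweighted edges is rejected.
    """
    if partitions < 1:
        raise InvalidInputError(f"partitions must be >= 1, got {partitions}")

    edge_map: dict[EdgeKey, float | None] = {}
    self_loops = 0
    saw_weighted = False
    saw_unweighted = False
    vertex_map: dict[str, Interactor] = {}

    for interaction in edges:
        if interaction.endpoint_a == interaction.endpoint_b:
            self_loops += 1
            continue
        if interaction.weight is None:
            saw_unweighted = True
        else:
            saw_weighted = True
        key = interaction.key
        if key in edge_map:
            old = edge_map[key]
            if interaction.weight is not None and (
                old is None or interaction.weight > old
            ):
                edge_map[key] = interaction.weight
        else:
            edge_map[key] = interaction.weight
        for endpoint in key:
            if endpoint not in vertex_map:
                vertex_map[endpoint] = Interactor(endpoint)

    if saw_weighted and saw_unweighted:
        raise InvalidInputError(
            "mixture of weighted and unweighted interactions"
        )
    if self_loops:
        logger.warning("%d self-loop(s) removed", self_loops)

    if vertices is not None:
        for interactor in vertices:
            vertex_map[interactor.id] = interactor

    if not edge_map and not vertex_map:
        raise InvalidInputError("cannot build a graph with no vertices and no edges")

    return MINGraph(
        vertices=vertex_map,
        edges=edge_map,
        labelled=saw_weighted,
        partitions=partitions,
    )


def induced_subgraph(g: MINGraph, node_set: Iterable[str]) -> MINGraph:
    """Vertex-induced subgraph: the given vertices plus all edges among them."""
    wanted = set(node_set)
    for identifier in wanted:
        if not g.has_vertex(identifier):
            raise UnknownInteractorError(identifier)
    vertices = {v: g.interactor(v) for v in wanted}
    edges = {
        key: w
        for key, w in g.edge_items()
        if key[0] in wanted and key[1] in wanted
    }
    return MINGraph(
        vertices=vertices,
        edges=edges,
        labelled=g.labelled,
        partitions=g.partitions,
    )
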