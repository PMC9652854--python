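"""Seeded synthetic network generation and independent brute-force oracles.

The generator produces connected preferential-attachment graphs whose
hub-dominated degree structure resembles real protein-interaction
networks, with optional i.i.d. edge labels in [0, 1].  The oracles are
deliberately naive reference implementations (path enumeration,
breadth-first search, union-find, pairwise connectivity probing) that
share no traversal code with the superstep-engine implementations, so
they can serve as ground truth in equivalence tests.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Union

import networkx as nx
import numpy as np

from .errors import InvalidParameterError
from .model import Interaction, MINGraph, build_graph

WeightDist = Union[str, tuple]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters for :func:`generate_min`.

    ``weight_dist`` is one of ``"uniform"``, ``("beta", alpha, beta)`` or
    ``("constant", w)``; string forms ``"beta:2,5"`` / ``"constant:0.8"``
    are accepted for CLI convenience.  Equal configs yield byte-identical
    graphs.
    """

    n: int
    attach: int = 2
    weight_dist: WeightDist = "uniform"
    labelled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("n must be >= 2")
        if self.attach < 1:
            raise InvalidParameterError("attach must be >= 1")
        if self.attach >= self.n:
            raise InvalidParameterError("attach must be < n")


def _parse_weight_dist(spec: WeightDist) -> tuple:
    if isinstance(spec, tuple):
        return spec
    if spec == "uniform":
        return ("uniform",)
    if ":" in spec:
        name, _, args = spec.partition(":")
        values = tuple(float(x) for x in args.split(","))
        return (name, *values)
    return (spec,)


def _draw_weights(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    name = dist[0]
    if name == "uniform":
        return rng.uniform(0.0, 1.0, size)
    if name == "beta":
        return rng.beta(dist[1], dist[2], size)
    if name == "constant":
        return np.full(size, float(dist[1]))
    raise InvalidParameterError(f"unknown weight distribution {dist[0]!r}")


def vertex_id(index: int) -> str:
    """Generated ids are "p000001", "p000002", ..."""
    return f"p{index + 1:06d}"


def generate_min(config: GeneratorConfig, partitions: int = 1) -> MINGraph:
    """Generate a connected preferential-attachment MIN.

    Deterministic under ``config.seed``: the skeleton comes from a seeded
    Barabasi-Albert process and weights are drawn in a fixed edge order.
    """
    skeleton = nx.barabasi_albert_graph(config.n, config.attach, seed=config.seed)
    edge_keys = sorted(tuple(sorted(e)) for e in skeleton.edges())
    if config.labelled:
        rng = np.random.default_rng(config.seed)
        weights = _draw_weights(
            rng, _parse_weight_dist(config.weight_dist), len(edge_keys)
        )
        interactions = [
            Interaction(vertex_id(a), vertex_id(b), float(w))
            for (a, b), w in zip(edge_keys, weights)
        ]
    else:
        interactions = [
            Interaction(vertex_id(a), vertex_id(b)) for a, b in edge_keys
        ]
    return build_graph(interactions, partitions=partitions)


# ---------------------------------------------------------------------------
# Oracles: independent reference implementations for equivalence testing.
# ---------------------------------------------------------------------------

_MAX_ENUM_VERTICES = 15


def oracle_max_product(g: MINGraph, i: str) -> dict[str, float]:
    """Best path product from ``i`` to every reachable vertex, by exhaustive
    simple-path enumeration.  Guarded to |V| <= 15."""
    if g.n_vertices > _MAX_ENUM_VERTICES:
        raise InvalidParameterError(
            f"oracle_max_product limited to {_MAX_ENUM_VERTICES} vertices"
        )
    g.interactor(i)
    adjacency = g.adjacency
    best: dict[str, float] = {}

    def walk(vertex: str, product: float, visited: set[str]) -> None:
        for neighbor, weight in adjacency[vertex].items():
            if neighbor in visited:
                continue
            p = product * weight
            if p > best.get(neighbor, -1.0):
                best[neighbor] = p
            walk(neighbor, p, visited | {neighbor})

    walk(i, 1.0, {i})
    return best


def oracle_khop(g: MINGraph, S: set[str], x: int) -> dict[str, int]:
    """Hop distances (<= x) from the source set, by plain queue BFS."""
    for identifier in S:
        g.interactor(identifier)
    adjacency = g.adjacency
    distance = {s: 0 for s in S}
    queue = deque(S)
    while queue:
        vertex = queue.popleft()
        d = distance[vertex]
        if d >= x:
            continue
        for neighbor in adjacency[vertex]:
            if neighbor not in distance:
                distance[neighbor] = d + 1
                queue.append(neighbor)
    return {v: d for v, d in distance.items() if v not in S}


def oracle_components(g: MINGraph) -> dict[str, str]:
    """Component labels (min member id) by union-find."""
    parent = {v: v for v in g.vertex_ids()}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for (a, b), _ in g.edge_items():
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots: dict[str, list[str]] = {}
    for v in parent:
        roots.setdefault(find(v), []).append(v)
    labels: dict[str, str] = {}
    for members in roots.values():
        label = min(members)
        for v in members:
            labels[v] = label
    return labels


def _connected_within(g: MINGraph, allowed: set[str], s: str, t: str) -> bool:
    """Is there a path s -> t using only vertices in ``allowed``? (DFS)"""
    stack = [s]
    seen = {s}
    adjacency = g.adjacency
    while stack:
        vertex = stack.pop()
        if vertex == t:
            return True
        for neighbor in adjacency[vertex]:
            if neighbor in allowed and neighbor not in seen:
                seen.add(neighbor)
                stack.append(neighbor)
    return False


def oracle_dispersion(g: MINGraph, u: str, v: str) -> int:
    """Kleinberg dispersion by a double loop over common-neighbor pairs,
    probing connectivity per pair inside u's neighborhood minus {u, v}."""
    shared = sorted((g.neighbors(u) & g.neighbors(v)) - {u, v})
    allowed = g.neighbors(u) - {u, v}
    value = 0
    for index, s in enumerate(shared):
        for t in shared[index + 1:]:
            if not _connected_within(g, allowed, s, t):
                value += 1
    return value
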