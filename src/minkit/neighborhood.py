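"""Hop-limited and weighted max-product-threshold neighborhoods.

Two query families over a MIN:

* ``x_neighbors`` — all vertices within ``x`` hops of a source set
  (edge labels ignored);
* ``x_weighted_neighbors`` — all vertices reachable from a single source by
  some path whose product of edge labels is strictly greater than ``x``.

Both are executed as superstep programs; the weighted query prunes
propagation at the threshold, which is sound because labels lie in [0, 1]
and path products can only shrink.  The corresponding ``*_subgraph``
variants return the vertex-induced subgraph over sources plus members.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import (
    INF,
    hop_distance_program,
    max_product_program,
    run_supersteps,
)
from .errors import InvalidParameterError, WrongModeError
from .model import MINGraph, induced_subgraph


@dataclass
class NeighborhoodResult:
    """Outcome of a neighborhood query.

    ``best_value`` maps each member to its hop distance (unweighted query)
    or to the maximum path product reaching it (weighted query).  Sources
    are never members of their own neighborhood.
    """

    source_set: frozenset[str]
    threshold: float
    members: set[str]
    best_value: dict[str, float]


def x_neighbors(
    g: MINGraph,
    S: set[str],
    x: int,
    executor: str = "serial",
    workers: int = 1,
) -> NeighborhoodResult:
    """Vertices (outside ``S``) whose hop distance to the nearest source
    is at most ``x``."""
    if not isinstance(x, int) or isinstance(x, bool) or x < 1:
        raise InvalidParameterError(f"x must be an integer >= 1, got {x!r}")
    sources = set(S)
    for identifier in sources:
        g.interactor(identifier)
    # x propagation rounds after superstep 0 reach exactly distance x.
    result = run_supersteps(
        g,
        hop_distance_program(sources, max_iterations=x + 1),
        executor=executor,
        workers=workers,
    )
    best = {
        v: int(d)
        for v, d in result.states.items()
        if v not in sources and d != INF and d <= x
    }
    return NeighborhoodResult(
        source_set=frozenset(sources),
        threshold=float(x),
        members=set(best),
        best_value=best,
    )


def x_subgraph(
    g: MINGraph,
    S: set[str],
    x: int,
    executor: str = "serial",
    workers: int = 1,
) -> MINGraph:
    """Induced subgraph over ``S`` and its x-hop neighbors."""
    result = x_neighbors(g, S, x, executor=executor, workers=workers)
    return induced_subgraph(g, result.members | result.source_set)


def x_weighted_neighbors(
    g: MINGraph,
    i: str,
    x: float,
    executor: str = "serial",
    workers: int = 1,
) -> NeighborhoodResult:
    """Vertices whose best path product from ``i`` is strictly > ``x``.

    The best value recorded per member is the maximum over all simple
    paths of the product of edge labels along the path.
    """
    if not g.labelled:
        raise WrongModeError("x_weighted_neighbors requires a labelled graph")
    if not (0.0 < x < 1.0):
        raise InvalidParameterError(f"x must be in (0, 1), got {x!r}")
    g.interactor(i)
    result = run_supersteps(
        g,
        max_product_program(i, threshold=x),
        executor=executor,
        workers=workers,
    )
    best = {v: p for v, p in result.states.items() if v != i and p > x}
    return NeighborhoodResult(
        source_set=frozenset({i}),
        threshold=float(x),
        members=set(best),
        best_value=best,
    )


def x_weighted_subgraph(
    g: MINGraph,
    i: str,
    x: float,
    executor: str = "serial",
    workers: int = 1,
) -> MINGraph:
    """Induced subgraph over ``i`` and its x-weighted neighbors."""
    result = x_weighted_neighbors(g, i, x, executor=executor, workers=workers)
    return induced_subgraph(g, result.members | {i})
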