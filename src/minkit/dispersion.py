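"""Kleinberg dispersion between two interactors.

K(u, v) counts the pairs of common neighbors of u and v that fall into
different connected components of the subgraph induced by the neighbors of
u with u and v removed.  A high value means the common neighborhood of the
pair is poorly connected inside u's neighborhood; it is 0 exactly when all
common neighbors share one component (or there are fewer than two of them).

Note that K is not symmetric: the induced graph is built from u's
neighborhood, so K(u, v) and K(v, u) may differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .components import connected_components
from .errors import InvalidParameterError
from .model import MINGraph, induced_subgraph


@dataclass
class DispersionResult:
    u: str
    v: str
    common_neighbors: set[str]
    cardinality: int
    value: int


def common_neighbors(g: MINGraph, u: str, v: str) -> set[str]:
    """Neighbors of both u and v, excluding u and v themselves."""
    if u == v:
        raise InvalidParameterError("u and v must be distinct")
    shared = g.neighbors(u) & g.neighbors(v)
    shared.discard(u)
    shared.discard(v)
    return shared


def dispersion(
    g: MINGraph, u: str, v: str, ordered: bool = False
) -> DispersionResult:
    """Kleinberg dispersion K(u, v).

    By default each unordered pair {s, t} is counted once; ``ordered=True``
    switches to the ordered-sum convention, which doubles every value.
    """
    shared = common_neighbors(g, u, v)
    hood = g.neighbors(u) - {u, v}
    labeling = connected_components(induced_subgraph(g, hood))
    value = sum(
        1
        for s, t in itertools.combinations(sorted(shared), 2)
        if labeling.labels[s] != labeling.labels[t]
    )
    if ordered:
        value *= 2
    return DispersionResult(
        u=u,
        v=v,
        common_neighbors=shared,
        cardinality=len(shared),
        value=value,
    )
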