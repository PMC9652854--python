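"""Connected components and component-vs-set queries.

A component is labelled by its lexicographically minimum member id; the
labeling is computed with the engine's min-label propagation program.
``closest_component`` and ``intersection_by_component`` implement the
component-overlap queries against a query set of interactors, with the
partition fixed to connected components (the general-partition form is
available as :func:`closest_block` for testing).
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import min_label_program, run_supersteps
from .model import MINGraph


@dataclass
class ComponentLabeling:
    """Association interactor id -> component id (minimum member id)."""

    labels: dict[str, str]

    def blocks(self) -> dict[str, set[str]]:
        """Component id -> member set."""
        out: dict[str, set[str]] = {}
        for vertex, label in self.labels.items():
            out.setdefault(label, set()).add(vertex)
        return out


def connected_components(
    g: MINGraph, executor: str = "serial", workers: int = 1
) -> ComponentLabeling:
    """Label every vertex with the minimum id of its connected component."""
    result = run_supersteps(
        g, min_label_program(), executor=executor, workers=workers
    )
    return ComponentLabeling(labels=dict(result.states))


def closest_block(blocks: dict[str, set[str]], S: set[str]) -> set[str]:
    """The block maximizing |block ∩ S|; ties broken by smaller block id."""
    best_id = min(
        blocks,
        key=lambda block_id: (-len(blocks[block_id] & S), block_id),
    )
    return set(blocks[best_id])


def closest_component(
    g: MINGraph,
    S: set[str],
    executor: str = "serial",
    workers: int = 1,
) -> set[str]:
    """Member set of the connected component with the largest overlap with
    ``S``; ties broken by smaller component id."""
    query = set(S)
    for identifier in query:
        g.interactor(identifier)
    labeling = connected_components(g, executor=executor, workers=workers)
    return closest_block(labeling.blocks(), query)


def intersection_by_component(
    g: MINGraph,
    S: set[str],
    executor: str = "serial",
    workers: int = 1,
) -> list[tuple[str, int]]:
    """(component id, |component ∩ S|) for every component, ordered by id.

    Size-0 intersections are included; the sizes sum to |S|.
    """
    query = set(S)
    for identifier in query:
        g.interactor(identifier)
    labeling = connected_components(g, executor=executor, workers=workers)
    blocks = labeling.blocks()
    return [
        (block_id, len(blocks[block_id] & query))
        for block_id in sorted(blocks)
    ]
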