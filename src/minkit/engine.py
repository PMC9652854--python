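"""Vertex-centric superstep execution (bulk-synchronous, Pregel-style).

A :class:`SuperstepProgram` bundles three user functions:

* ``vprog(vertex_id, state, merged_message) -> new state`` — vertex update;
* ``send_msg(triplet) -> iterable of (target id, message)`` — message
  generation, evaluated on edge triplets;
* ``merge_msg(m1, m2) -> m`` — combination of messages addressed to the
  same vertex; it MUST be commutative and associative, since delivery
  order is unspecified (and differs between executors).

Execution proceeds in supersteps.  Superstep 0 applies ``vprog`` with
``initial_message`` at every vertex and then evaluates ``send_msg`` on every
triplet.  Each later superstep merges the pending messages per target,
applies ``vprog`` only at vertices that received a message, and evaluates
``send_msg`` on triplets incident to vertices whose state changed.  The run
halts when no messages are produced or ``max_iterations`` supersteps have
executed.  Messages produced in superstep *t* are visible only in *t + 1*.

Two executors are provided — a serial reference and a partitioned one that
fans the send phase out over worker threads, one edge partition at a time.
Both are bound to the same observable contract: identical
:class:`VertexStates` for any worker/partition count.
"""

from __future__ import annotations

import itertools
import random
from collections.abc import Callable, Iterable, Sequence
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any, NamedTuple

from .errors import ContractViolationError, InvalidParameterError
from .model import EdgeKey, MINGraph

Message = Any
State = Any


class Triplet(NamedTuple):
    """One directed view of an edge offered to ``send_msg``."""

    src: str
    src_state: State
    dst: str
    dst_state: State
    weight: float | None


@dataclass
class SuperstepProgram:
    """User program for :func:`run_supersteps`.

    ``direction`` controls how each undirected edge is presented: ``"both"``
    offers two triplets per edge (one per orientation), ``"out"`` only the
    canonical orientation, ``"in"`` only the reverse.

    ``message_samples`` (optional) enables a randomized commutativity /
    associativity check of ``merge_msg`` at construction time.
    """

    initial_state: Callable[[str], State]
    initial_message: Message
    vprog: Callable[[str, State, Message], State]
    send_msg: Callable[[Triplet], Iterable[tuple[str, Message]]]
    merge_msg: Callable[[Message, Message], Message]
    max_iterations: int | None = None
    direction: str = "both"
    message_samples: Sequence[Message] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.direction not in ("both", "out", "in"):
            raise InvalidParameterError(
                f"direction must be both/out/in, got {self.direction!r}"
            )
        if self.max_iterations is not None and self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")
        if len(self.message_samples) >= 2:
            self._check_merge_algebra()

    def _check_merge_algebra(self) -> None:
        rng = random.Random(0)
        samples = list(self.message_samples)
        for _ in range(50):
            a, b, c = (rng.choice(samples) for _ in range(3))
            if not _values_equal(self.merge_msg(a, b), self.merge_msg(b, a)):
                raise ContractViolationError(
                    f"merge_msg is not commutative on {a!r}, {b!r}"
                )
            left = self.merge_msg(self.merge_msg(a, b), c)
            right = self.merge_msg(a, self.merge_msg(b, c))
            if not _values_equal(left, right):
                raise ContractViolationError(
                    f"merge_msg is not associative on {a!r}, {b!r}, {c!r}"
                )


@dataclass
class VertexStates:
    """Final per-vertex states plus the number of supersteps executed."""

    states: dict[str, State]
    supersteps_executed: int


def _values_equal(x: Any, y: Any) -> bool:
    try:
        return bool(x == y)
    except Exception as exc:  # states must be value-comparable
        raise ContractViolationError(
            f"states/messages are not value-comparable: {exc}"
        ) from exc


def _triplets_for_edge(
    key: EdgeKey, weight: float | None, states: dict[str, State], direction: str
) -> Iterable[Triplet]:
    a, b = key
    if direction in ("both", "out"):
        yield Triplet(a, states[a], b, states[b], weight)
    if direction in ("both", "in"):
        yield Triplet(b, states[b], a, states[a], weight)


def _send_over_edges(
    edge_keys: Iterable[EdgeKey],
    g: MINGraph,
    states: dict[str, State],
    program: SuperstepProgram,
    changed: set[str] | None,
) -> dict[str, Message]:
    """Evaluate send_msg on (a subset of) edges; merge messages per target.

    ``changed = None`` means all edges (superstep 0); otherwise only edges
    incident to a changed vertex are offered.
    """
    merged: dict[str, Message] = {}
    merge = program.merge_msg
    checked = 0
    for key in edge_keys:
        if changed is not None and key[0] not in changed and key[1] not in changed:
            continue
        w = g._edges[key]
        for triplet in _triplets_for_edge(key, w, states, program.direction):
            for target, message in program.send_msg(triplet):
                if target in merged:
                    if checked < 8:  # spot-check commutativity at runtime
                        if not _values_equal(
                            merge(merged[target], message),
                            merge(message, merged[target]),
                        ):
                            raise ContractViolationError(
                                "merge_msg is not commutative"
                            )
                        checked += 1
                    merged[target] = merge(merged[target], message)
                else:
                    merged[target] = message
    return merged


def _merge_dicts(
    parts: Iterable[dict[str, Message]],
    merge: Callable[[Message, Message], Message],
) -> dict[str, Message]:
    out: dict[str, Message] = {}
    for part in parts:
        for target, message in part.items():
            if target in out:
                out[target] = merge(out[target], message)
            else:
                out[target] = message
    return out


def run_supersteps(
    g: MINGraph,
    program: SuperstepProgram,
    executor: str = "serial",
    workers: int = 1,
) -> VertexStates:
    """Run a superstep program to completion on ``g``.

    ``executor`` is ``"serial"`` or ``"parallel"``; the parallel executor
    splits the send phase by edge partition across ``workers`` threads.
    Results are identical for any executor/workers/partitions combination.
    """
    if executor not in ("serial", "parallel"):
        raise InvalidParameterError(f"unknown executor {executor!r}")
    if workers < 1:
        raise InvalidParameterError("workers must be >= 1")

    states = {v: program.initial_state(v) for v in g.vertex_ids()}

    # Superstep 0: vprog everywhere with the initial message.
    changed: set[str] | None = None
    for v in states:
        new = program.vprog(v, states[v], program.initial_message)
        states[v] = new
    supersteps = 1

    partition_groups = g.edges_by_partition() if executor == "parallel" else None
    pool = (
        ThreadPoolExecutor(max_workers=workers)
        if executor == "parallel" and workers > 1
        else None
    )
    try:
        while True:
            if executor == "serial":
                inbox = _send_over_edges(g._edges, g, states, program, changed)
            else:
                assert partition_groups is not None
                if pool is not None:
                    parts = pool.map(
                        lambda keys: _send_over_edges(
                            keys, g, states, program, changed
                        ),
                        partition_groups,
                    )
                else:
                    parts = (
                        _send_over_edges(keys, g, states, program, changed)
                        for keys in partition_groups
                    )
                inbox = _merge_dicts(parts, program.merge_msg)

            if not inbox:
                break
            if (
                program.max_iterations is not None
                and supersteps >= program.max_iterations
            ):
                break

            changed = set()
            for v, message in inbox.items():
                new = program.vprog(v, states[v], message)
                if not _values_equal(new, states[v]):
                    states[v] = new
                    changed.add(v)
            supersteps += 1
            if not changed:
                break
    finally:
        if pool is not None:
            pool.shutdown(wait=True)

    return VertexStates(states=states, supersteps_executed=supersteps)


# ---------------------------------------------------------------------------
# Bundled programs.  All update states by min/max of products or sums of
# input values, so exact float comparison for change detection is stable.
# ---------------------------------------------------------------------------

INF = float("inf")


def min_label_program(max_iterations: int | None = None) -> SuperstepProgram:
    """Label propagation: every vertex converges to the minimum id reachable
    from it — the standard connected-components program."""
    return SuperstepProgram(
        initial_state=lambda v: v,
        initial_message=None,
        vprog=lambda v, s, m: s if m is None else min(s, m),
        send_msg=lambda t: [(t.dst, t.src_state)] if t.src_state < t.dst_state else [],
        merge_msg=min,
        max_iterations=max_iterations,
        message_samples=("a", "b", "uniprotkb:P04637", "zz"),
    )


def hop_distance_program(
    sources: set[str], max_iterations: int | None = None
) -> SuperstepProgram:
    """Multi-source breadth-first hop distances (unweighted)."""
    return SuperstepProgram(
        initial_state=lambda v: 0 if v in sources else INF,
        initial_message=INF,
        vprog=lambda v, s, m: min(s, m),
        send_msg=lambda t: (
            [(t.dst, t.src_state + 1)] if t.src_state + 1 < t.dst_state else []
        ),
        merge_msg=min,
        max_iterations=max_iterations,
        message_samples=(0, 1, 2, 5, INF),
    )


def max_product_program(source: str, threshold: float = 0.0) -> SuperstepProgram:
    """Best path-label-product propagation from ``source``.

    States start at 1.0 at the source and 0.0 elsewhere; a message
    ``state * weight`` is forwarded only when it beats both the threshold
    and the target's current best.  Labels are <= 1, so products never
    increase along a path and the propagation converges to the maximum
    over all simple paths.
    """

    def send(t: Triplet) -> list[tuple[str, Message]]:
        p = t.src_state * t.weight
        if p > threshold and p > t.dst_state:
            return [(t.dst, p)]
        return []

    return SuperstepProgram(
        initial_state=lambda v: 1.0 if v == source else 0.0,
        initial_message=0.0,
        vprog=lambda v, s, m: max(s, m),
        send_msg=send,
        merge_msg=max,
        message_samples=(0.0, 0.25, 0.5, 0.9, 1.0),
    )
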