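import random

import pytest

from minkit.model import Interaction, Interactor, build_graph


@pytest.fixture
def g1():
    """Weighted fixture: a-b 0.9, b-c 0.8, a-c 0.5, c-d 0.6."""
    return build_graph([
        Interaction("a", "b", 0.9),
        Interaction("b", "c", 0.8),
        Interaction("a", "c", 0.5),
        Interaction("c", "d", 0.6),
    ])


@pytest.fixture
def g2():
    """Unweighted fixture with components {a, b} and {c, d, e}."""
    return build_graph([
        Interaction("a", "b"),
        Interaction("c", "d"),
        Interaction("d", "e"),
    ])


@pytest.fixture
def g3():
    """Dispersion fixture: u and v share neighbors s1..s4; s1-s2 connected."""
    return build_graph([
        Interaction("u", "s1"), Interaction("u", "s2"),
        Interaction("u", "s3"), Interaction("u", "s4"),
        Interaction("v", "s1"), Interaction("v", "s2"),
        Interaction("v", "s3"), Interaction("v", "s4"),
        Interaction("u", "v"),
        Interaction("s1", "s2"),
    ])


def random_graph(rng: random.Random, n: int, p: float = 0.3,
                 weighted: bool = True, partitions: int = 1):
    """Erdos-Renyi-style random graph over ids v00..; may be disconnected."""
    ids = [f"v{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = round(rng.uniform(0.05, 1.0), 3) if weighted else None
                edges.append(Interaction(ids[i], ids[j], w))
    if not edges:  # keep weighted graphs labelled
        w = round(rng.uniform(0.05, 1.0), 3) if weighted else None
        edges.append(Interaction(ids[0], ids[1], w))
    vertices = [Interactor(v) for v in ids]
    return build_graph(edges, vertices, partitions=partitions)
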