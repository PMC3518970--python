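import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mesoconn.connectome import Arc, Connectome

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_connectome(nodes, pairs, weights=None):
    nodes = list(nodes)
    if weights is None:
        weights = [1] * len(pairs)
    return Connectome(
        nodes=nodes,
        arcs={(s, t): Arc(weight=w) for (s, t), w in zip(pairs, weights)},
    )


def random_connectome(rng: np.random.Generator, n: int, p: float) -> Connectome:
    nodes = [f"v{i}" for i in range(n)]
    arcs = {}
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                arcs[(nodes[i], nodes[j])] = Arc(weight=int(rng.integers(1, 10)))
    return Connectome(nodes=nodes, arcs=arcs)


@pytest.fixture
def three_cycle():
    return make_connectome("ABC", [("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def complete3():
    return make_connectome(
        "ABC",
        [(a, b) for a in "ABC" for b in "ABC" if a != b],
    )


@pytest.fixture
def reciprocal_pair():
    return make_connectome("AB", [("A", "B"), ("B", "A")])


@pytest.fixture
def fixture8():
    from mesoconn.synthetic import fixture_small

    return fixture_small()


@pytest.fixture
def binary_tree_doc():
    """3-level balanced binary tree: 7 regions, leaves d,e,f,g in DF order."""
    return {
        "id": "a",
        "children": [
            {"id": "b", "children": [{"id": "d"}, {"id": "e"}]},
            {"id": "c", "children": [{"id": "f"}, {"id": "g"}]},
        ],
    }
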