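import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from prorankplus import PPINetwork


@pytest.fixture
def triangle() -> PPINetwork:
    return PPINetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> PPINetwork:
    return PPINetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def k4() -> PPINetwork:
    edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
    return PPINetwork.from_edges(edges)


@pytest.fixture
def star4() -> PPINetwork:
    """Hub with three leaves."""
    return PPINetwork.from_edges([("hub", "x"), ("hub", "y"), ("hub", "z")])


@pytest.fixture
def two_shared_triangles() -> PPINetwork:
    """Two unit-weight triangles {a,b,c} and {c,d,e} sharing only c."""
    edges = [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("c", "e"), ("d", "e")]
    return PPINetwork.from_edges(edges)


def clique_edges(names):
    from itertools import combinations

    return list(combinations(names, 2))
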