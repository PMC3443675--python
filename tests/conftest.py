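import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import netmod as nm


@pytest.fixture
def triangle():
    g = nm.new_graph()
    nm.add_edge(g, "a", "b")
    nm.add_edge(g, "b", "c")
    nm.add_edge(g, "a", "c")
    return g


@pytest.fixture
def two_triangles_bridge():
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge edge c-d."""
    g = nm.new_graph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c"),
                 ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]:
        nm.add_edge(g, u, v)
    return g


@pytest.fixture
def path_abc():
    g = nm.new_graph()
    nm.add_edge(g, "a", "b")
    nm.add_edge(g, "b", "c")
    return g


@pytest.fixture
def toy_records():
    """Three records over two sources yielding two distinct pairs."""
    return [
        nm.InteractionRecord("1", "2", "X"),
        nm.InteractionRecord("2", "1", "Y"),   # same pair, second source
        nm.InteractionRecord("2", "3", "X"),
    ]


@pytest.fixture
def identity_map():
    return nm.IdMap.identity([str(i) for i in range(1, 10)])
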