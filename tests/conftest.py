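import numpy as np
import pytest

from forceatlas2 import Graph, LayoutSettings


@pytest.fixture
def path_graph():
    """a - b - c path."""
    return Graph.from_edge_pairs([("a", "b"), ("b", "c")])


@pytest.fixture
def two_node_graph():
    return Graph.from_edge_pairs([("a", "b")])


@pytest.fixture
def defaults():
    return LayoutSettings()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
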