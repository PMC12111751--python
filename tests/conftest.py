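import networkx as nx
import pytest


@pytest.fixture
def toy_graph():
    """5-node worked example: A:2.0 B:1.5 C:-1.0 D:0.5 E:-2.0."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("A", "E")])
    weights = {"A": 2.0, "B": 1.5, "C": -1.0, "D": 0.5, "E": -2.0}
    return g, weights


@pytest.fixture
def small_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("S1\tdesc\tA\tB\nS2\tdesc\tC\tD\tE\n")
    return p
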