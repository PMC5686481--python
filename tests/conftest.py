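import pytest

from randnet import Graph, build_graph


@pytest.fixture
def path_graph() -> Graph:
    """Path a-b-c."""
    return build_graph(["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def k4() -> Graph:
    nodes = ["a", "b", "c", "d"]
    edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    return build_graph(nodes, edges)


def make_table(attr_values):
    """Attribute table from {attr: {node: value}}."""
    table = {}
    for attr, per_node in attr_values.items():
        for node, value in per_node.items():
            table.setdefault(node, {})[attr] = value
    return table


@pytest.fixture
def toy_tables():
    """Two small attribute tables sharing the 'Degree' attribute."""
    t1 = make_table({"Degree": {"a": 1, "b": 2, "c": 1},
                     "Eccentricity": {"a": 2, "b": 1, "c": 2}})
    t2 = make_table({"Degree": {"x": 2, "y": 2, "z": 2}})
    return t1, t2
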