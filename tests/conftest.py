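import networkx as nx
import pytest

from nasfinder.interactome import OTHER, REFERENCE, InteractomeNetwork


def make_net(edges, roles=None, provenance=REFERENCE):
    """Build a small InteractomeNetwork from edge pairs and a role mapping."""
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, provenance=provenance)
    nx.set_node_attributes(g, OTHER, "role")
    for gene, role in (roles or {}).items():
        g.add_node(gene)
        g.nodes[gene]["role"] = role
    return InteractomeNetwork(g)


@pytest.fixture
def g1():
    """The worked 4-node graph: edges a-b, a-c, b-c, b-d."""
    return make_net([("a", "b"), ("a", "c"), ("b", "c"), ("b", "d")])


@pytest.fixture
def write_tsv(tmp_path):
    counter = iter(range(1000))

    def _write(lines, name=None):
        path = tmp_path / (name or f"fixture{next(counter)}.tsv")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
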