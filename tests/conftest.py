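import pytest

from hetpath.hetnet import Edge, HetNet, Node
from hetpath.metagraph import MetaEdge, Metagraph
from hetpath.synthetic import SynthConfig, generate_dataset
from hetpath.temporal import assign_edge_years, slice_series


@pytest.fixture(scope="session")
def toy_metagraph() -> Metagraph:
    """Compound/Disease schema with TREATS plus two similarity metaedges."""
    return Metagraph(
        node_types={"Compound": "CD", "Disease": "DO"},
        metaedges=[
            MetaEdge("Compound", "TREATS", "Disease", "t", True),
            MetaEdge("Compound", "RELATED_TO", "Compound", "rt", False),
            MetaEdge("Disease", "ASSOCIATED_WITH", "Disease", "aw", False),
        ],
    )


@pytest.fixture
def toy_net(toy_metagraph) -> HetNet:
    """C1-rt-C2, C2-t->D1, C1-t->D1: one conforming CDrtCDtDO path."""
    nodes = [
        Node("C1", "compound one", "Compound"),
        Node("C2", "compound two", "Compound"),
        Node("D1", "disease one", "Disease"),
    ]
    edges = [
        Edge("C1", "C2", "CDrtCD", frozenset({"p1"})),
        Edge("C2", "D1", "CDtDO", frozenset({"p2"})),
        Edge("C1", "D1", "CDtDO", frozenset({"p3"})),
    ]
    return HetNet(toy_metagraph, nodes, edges)


@pytest.fixture(scope="session")
def default_study():
    """One realisation of the default synthetic study (planted signal)."""
    return generate_dataset(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def sliced_study(default_study):
    """The default study dated and sliced every 5 years, 1960-2015."""
    net, _report = assign_edge_years(default_study.net, default_study.year_map)
    slices = slice_series(net, range(1960, 2016, 5))
    return slices, default_study.indications
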