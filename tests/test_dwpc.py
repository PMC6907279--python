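"""DWPC engine: weighted adjacencies, matrix-vs-oracle agreement, features."""

import numpy as np
import pytest

from hetpath.dwpc import (
    FeatureConfig,
    dwpc_matrix,
    dwpc_oracle,
    extract_features,
    weighted_adjacency,
)
from hetpath.errors import BudgetError, IdentifierError
from hetpath.hetnet import Edge, HetNet, Node
from hetpath.metagraph import Metapath, enumerate_metapaths
from hetpath.synthetic import SynthConfig, generate_temporal_hetnet

TOY_DWPC = 2.0 ** -0.4  # single path C1-rt-C2-t->D1, step degrees (1*1), (1*2)


def test_weighted_adjacency_hand_example(toy_metagraph):
    # adjacency [[1,1],[0,1]]: source degrees 2,1; target degrees 1,2; w=1
    nodes = [
        Node("C1", "", "Compound"),
        Node("C2", "", "Compound"),
        Node("D1", "", "Disease"),
        Node("D2", "", "Disease"),
    ]
    net = HetNet(
        toy_metagraph,
        nodes,
        [
            Edge("C1", "D1", "CDtDO"),
            Edge("C1", "D2", "CDtDO"),
            Edge("C2", "D2", "CDtDO"),
        ],
    )
    m = weighted_adjacency(net, "CDtDO", "forward", w=1.0).toarray()
    assert np.allclose(m, [[0.5, 0.25], [0.0, 0.5]])
    # w = 0 turns damping off: exact 0/1 adjacency
    m0 = weighted_adjacency(net, "CDtDO", "forward", w=0.0).toarray()
    assert np.array_equal(m0, [[1, 1], [0, 1]])


def test_isolated_node_gives_zero_row(toy_metagraph):
    nodes = [
        Node("C1", "", "Compound"),
        Node("C2", "", "Compound"),
        Node("D1", "", "Disease"),
    ]
    net = HetNet(toy_metagraph, nodes, [Edge("C2", "D1", "CDtDO")])
    m = weighted_adjacency(net, "CDtDO", "forward", w=0.4).toarray()
    assert np.all(m[0] == 0)  # C1 row


def test_weighted_adjacency_unknown_metaedge(toy_net):
    with pytest.raises(IdentifierError):
        weighted_adjacency(toy_net, "CDxDO", "forward", 0.4)


def test_worked_dwpc_cell(toy_net, toy_metagraph):
    """The 3-node toy yields DWPC = 2^-0.4 for CDrtCDtDO at w=0.4."""
    mp = Metapath.parse(toy_metagraph, "CDrtCDtDO")
    i = toy_net.node_ids("Compound").index("C1")
    j = toy_net.node_ids("Disease").index("D1")
    from_matrix = dwpc_matrix(toy_net, mp, 0.4).toarray()[i, j]
    from_oracle = dwpc_oracle(toy_net, "C1", "D1", mp, 0.4)
    assert from_matrix == pytest.approx(TOY_DWPC, abs=1e-12)
    assert from_oracle == pytest.approx(TOY_DWPC, abs=1e-12)
    assert abs(from_matrix - from_oracle) < 1e-10


def test_backtracking_walk_is_not_a_path(toy_metagraph):
    """CDrtCDrtCD from C1 to C1 revisits C1: node-distinctness gives 0."""
    nodes = [Node("C1", "", "Compound"), Node("C2", "", "Compound")]
    net = HetNet(toy_metagraph, nodes, [Edge("C1", "C2", "CDrtCD")])
    mp = Metapath.parse(toy_metagraph, "CDrtCDrtCD")
    i = net.node_ids("Compound").index("C1")
    assert dwpc_matrix(net, mp, 0.4).toarray()[i, i] == 0
    assert dwpc_oracle(net, "C1", "C1", mp, 0.4) == 0


def test_no_conforming_path_gives_zero(toy_metagraph):
    nodes = [Node("C1", "", "Compound"), Node("D1", "", "Disease")]
    net = HetNet(toy_metagraph, nodes, [])
    mp = Metapath.parse(toy_metagraph, "CDtDO")
    assert dwpc_oracle(net, "C1", "D1", mp, 0.4) == 0


def _small_random_net(seed):
    return generate_temporal_hetnet(
        SynthConfig(
            seed=seed,
            n_nodes={"Compound": 14, "Disease": 10, "Gene": 8, "Anatomy": 5},
            mean_degree={
                "CDtDO": 1.5,
                "CDrtCD": 2.0,
                "DOawDO": 2.0,
                "CDiwG": 1.5,
                "GawDO": 1.5,
                "AloCD": 3.0,
                "AloDO": 3.0,
            },
        )
    )[0]


@pytest.mark.parametrize("seed", [0, 1])
@pytest.mark.parametrize("w", [0.0, 0.4])
def test_matrix_engine_equals_oracle_on_random_nets(seed, w):
    net = _small_random_net(seed)
    srcs, tgts = net.node_ids("Compound"), net.node_ids("Disease")
    for mp in enumerate_metapaths(net.metagraph, "Compound", "Disease", 3):
        m = dwpc_matrix(net, mp, w).toarray()
        for i, s in enumerate(srcs):
            for j, t in enumerate(tgts):
                assert abs(m[i, j] - dwpc_oracle(net, s, t, mp, w)) < 1e-10
        if w == 0:  # damping off: exact node-distinct path counts
            assert np.allclose(m, np.round(m))


def test_dwpc_non_increasing_in_damping(toy_net, toy_metagraph):
    mp = Metapath.parse(toy_metagraph, "CDrtCDtDO")
    values = [
        dwpc_oracle(toy_net, "C1", "D1", mp, w) for w in (0.0, 0.2, 0.4, 0.8, 1.0)
    ]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_extra_edges_at_intermediate_nodes_shrink_path_weight(toy_metagraph):
    """Raising an intermediate node's degree dilutes the path (w > 0)."""
    mp = Metapath.parse(toy_metagraph, "CDrtCDtDO")
    nodes = [
        Node("C1", "", "Compound"),
        Node("C2", "", "Compound"),
        Node("D1", "", "Disease"),
        Node("D2", "", "Disease"),
    ]
    base = HetNet(
        toy_metagraph,
        nodes,
        [Edge("C1", "C2", "CDrtCD"), Edge("C2", "D1", "CDtDO")],
    )
    bulkier = base.with_edges([Edge("C2", "D2", "CDtDO")])
    assert dwpc_oracle(bulkier, "C1", "D1", mp, 0.4) < dwpc_oracle(
        base, "C1", "D1", mp, 0.4
    )


def test_oracle_budget_guard():
    net = _small_random_net(3)
    mp = enumerate_metapaths(net.metagraph, "Compound", "Disease", 3)[-1]
    s = net.node_ids("Compound")[0]
    t = net.node_ids("Disease")[0]
    with pytest.raises(BudgetError):
        dwpc_oracle(net, s, t, mp, 0.4, max_paths=1)


# ------------------------------------------------------------------ features
def test_feature_table_matches_oracle_cell_by_cell(toy_net):
    cfg = FeatureConfig("Compound", "Disease", w=0.4, max_length=2)
    pairs = [("C1", "D1"), ("C2", "D1")]
    table = extract_features(toy_net, pairs, cfg)
    for mp in cfg.metapaths(toy_net):
        for pair in pairs:
            expected = dwpc_oracle(toy_net, pair[0], pair[1], mp, 0.4)
            assert table.loc[pair, f"dwpc_{mp.label}"] == pytest.approx(
                expected, abs=1e-10
            )
    assert table.loc[("C1", "D1"), "degree_source_CDtDO"] == 1
    assert table.loc[("C1", "D1"), "degree_source_CDrtCD"] == 1
    assert table.loc[("C1", "D1"), "degree_target_CDtDO"] == 2
    assert table.loc[("C1", "D1"), "degree_target_DOawDO"] == 0


def test_disconnected_pair_has_all_zero_features(toy_metagraph):
    nodes = [
        Node("C1", "", "Compound"),
        Node("C2", "", "Compound"),
        Node("D1", "", "Disease"),
        Node("D2", "", "Disease"),
    ]
    net = HetNet(toy_metagraph, nodes, [Edge("C1", "D1", "CDtDO")])
    cfg = FeatureConfig("Compound", "Disease", w=0.4, max_length=3)
    table = extract_features(net, [("C2", "D2")], cfg)
    assert (table.to_numpy() == 0).all()


def test_hub_drug_features_are_damped_toward_zero(toy_metagraph):
    """A promiscuous compound's paths carry weight near zero under damping."""
    nodes = [Node("H", "", "Compound"), Node("C2", "", "Compound"),
             Node("C3", "", "Compound"), Node("C4", "", "Compound")]
    nodes += [Node(f"D{i}", "", "Disease") for i in range(40)]
    edges = [Edge("H", f"D{i}", "CDtDO") for i in range(40)]
    edges += [
        Edge("C2", "H", "CDrtCD"),  # C2's only route to D1 runs through the hub
        Edge("C3", "C4", "CDrtCD"),
        Edge("C4", "D1", "CDtDO"),  # C3's route runs through an ordinary drug
    ]
    net = HetNet(toy_metagraph, nodes, edges)
    mp = Metapath.parse(toy_metagraph, "CDrtCDtDO")
    hub_value = dwpc_oracle(net, "C2", "D1", mp, 1.0)
    normal_value = dwpc_oracle(net, "C3", "D1", mp, 1.0)
    assert 0 < hub_value < 0.05 < normal_value  # 40 treats edges crush the weight


def test_removing_a_metaedge_zeroes_exactly_its_columns(default_study):
    net = default_study.net
    cfg = FeatureConfig("Compound", "Disease", w=0.4, max_length=2)
    pairs = [
        (c, d)
        for c in net.node_ids("Compound")[:8]
        for d in net.node_ids("Disease")[:8]
    ]
    stripped = net.filter_edges(lambda e: e.metaedge != "GawDO")
    before = extract_features(net, pairs, cfg)
    after = extract_features(stripped, pairs, cfg)
    for col in before.columns:
        if "GawDO" in col.replace("degree_source_", "").replace("degree_target_", ""):
            assert (after[col] == 0).all()
        elif col.startswith("dwpc_"):
            assert np.allclose(before[col], after[col])


def test_missing_pair_endpoint_reported(toy_net):
    cfg = FeatureConfig("Compound", "Disease", w=0.4, max_length=2)
    with pytest.raises(IdentifierError) as err:
        extract_features(toy_net, [("C1", "D1"), ("C9", "D1")], cfg)
    assert "C9" in str(err.value)
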