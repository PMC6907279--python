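"""Triple-table cleaning rules, each against a hand-traced expectation."""

import pandas as pd
import pytest

from hetpath.build import (
    DROP,
    build_network,
    condense_edge_types,
    filter_low_support_edges,
    filter_sparse_edge_types,
    remap_concepts,
    remove_hub_nodes,
    triples_to_hetnet,
)
from hetpath.errors import EmptyNetworkError, SchemaError
from hetpath.hetnet import Edge, HetNet, Node
from hetpath.io import write_hetnet

ABBREVS = {"Compound": "CD", "Disease": "DO"}


def triples(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "subject_type",
            "predicate",
            "object",
            "object_type",
            "pmids",
        ],
    ).assign(pmids=lambda df: df["pmids"].map(lambda v: frozenset(v.split("|"))))


# ------------------------------------------------------------------- remap
def test_remap_merges_concepts_and_unions_pmids():
    t = triples(
        [
            ("A", "Compound", "TREATS", "B", "Disease", "p1"),
            ("A2", "Compound", "TREATS", "B", "Disease", "p2"),
        ]
    )
    out, report = remap_concepts(t, {"A2": ("A", "drug A")})
    assert len(out) == 1
    assert out.iloc[0]["pmids"] == frozenset({"p1", "p2"})
    assert report["merged_triples"] == 1


def test_remap_many_granular_concepts_into_one():
    """Several granular disease ids collapse to a single canonical node."""
    variants = ["rhinitis_vasomotor", "rhinitis_perennial", "rhinitis_seasonal"]
    t = triples(
        [("X", "Compound", "TREATS", v, "Disease", f"p{i}") for i, v in enumerate(variants)]
        + [("X", "Compound", "TREATS", "rhinitis_allergic", "Disease", "p9")]
    )
    cm = {v: ("rhinitis_allergic", "Allergic rhinitis") for v in variants}
    out, _ = remap_concepts(t, cm)
    assert len(out) == 1
    assert set(out.iloc[0]["pmids"]) == {"p0", "p1", "p2", "p9"}
    net = triples_to_hetnet(out, ABBREVS, names={"rhinitis_allergic": "Allergic rhinitis"})
    assert net.nodes["rhinitis_allergic"].name == "Allergic rhinitis"


def test_remap_empty_map_is_identity_and_self_triples_drop():
    t = triples([("A", "Compound", "TREATS", "B", "Disease", "p1")])
    out, _ = remap_concepts(t, {})
    pd.testing.assert_frame_equal(out, t)
    out2, report = remap_concepts(t, {"B": ("A", "merged")})
    assert len(out2) == 0 and report["dropped_self_triples"] == 1


# ----------------------------------------------------------------- condense
def test_condense_prevents_into_treats_with_union():
    t = triples(
        [
            ("A", "Compound", "TREATS", "B", "Disease", "p1"),
            ("A", "Compound", "PREVENTS", "B", "Disease", "p2"),
        ]
    )
    out, _ = condense_edge_types(
        t, {("Compound", "PREVENTS", "Disease"): "TREATS"}
    )
    assert len(out) == 1
    assert out.iloc[0]["predicate"] == "TREATS"
    assert out.iloc[0]["pmids"] == frozenset({"p1", "p2"})


def test_condense_identity_and_drop():
    t = triples(
        [
            ("A", "Compound", "TREATS", "B", "Disease", "p1"),
            ("A", "Compound", "CAUSES", "B", "Disease", "p2"),
        ]
    )
    out, _ = condense_edge_types(t, {})
    # identity up to the canonical row sort applied by deduplication
    assert sorted(map(tuple, out.itertuples(index=False))) == sorted(
        map(tuple, t.itertuples(index=False))
    )
    out2, report = condense_edge_types(t, {("Compound", "CAUSES", "Disease"): DROP})
    assert list(out2["predicate"]) == ["TREATS"] and report["dropped_triples"] == 1


# ------------------------------------------------------------- sparse filter
def _counted_net(counts: dict[str, int]) -> HetNet:
    """A net with `counts[predicate]` Compound->Disease edges per metaedge."""
    rows = []
    for pred, n in counts.items():
        for i in range(n):
            rows.append((f"C{pred}{i}", "Compound", pred, f"D{pred}{i}", "Disease", "p"))
    return triples_to_hetnet(triples(rows), ABBREVS)


def test_sparse_filter_strict_inequality_boundary():
    # 1/1000 == 0.001 is NOT < 0.001: the type is kept
    net = _counted_net({"TREATS": 999, "CAUSES": 1})
    out = filter_sparse_edge_types(net, 0.001)
    assert set(out.metagraph.metaedge_abbrevs) == set(net.metagraph.metaedge_abbrevs)
    # 1/10000 < 0.001: removed
    net2 = _counted_net({"TREATS": 9999, "CAUSES": 1})
    out2 = filter_sparse_edge_types(net2, 0.001)
    assert [me.predicate for me in out2.metagraph.metaedges] == ["TREATS"]
    assert out2.n_edges == 9999


def test_sparse_filter_zero_fraction_is_identity():
    net = _counted_net({"TREATS": 5, "CAUSES": 1})
    assert filter_sparse_edge_types(net, 0.0) == net


# -------------------------------------------------------------- hub removal
def test_hub_removal_star_graph():
    rows = [("HUB", "Compound", "TREATS", f"D{i}", "Disease", "p") for i in range(4)]
    net = triples_to_hetnet(triples(rows), ABBREVS)
    out = remove_hub_nodes(net, 1)
    assert "HUB" not in out.nodes and out.n_edges == 0


def test_hub_removal_zero_is_identity_and_tie_break_is_lexicographic():
    # degrees: A=3, B=2, C=2, D=1 → remove A, then the lexicographically
    # smaller of the two degree-2 nodes (B)
    rows = [
        ("A", "Compound", "RELATED_TO", "B", "Compound", "p"),
        ("A", "Compound", "RELATED_TO", "C", "Compound", "p"),
        ("A", "Compound", "RELATED_TO", "D", "Compound", "p"),
        ("B", "Compound", "RELATED_TO", "C", "Compound", "p"),
    ]
    net = triples_to_hetnet(
        triples(rows), ABBREVS, undirected_predicates={"RELATED_TO"}
    )
    assert remove_hub_nodes(net, 0) == net
    out = remove_hub_nodes(net, 2)
    assert "A" not in out.nodes and "B" not in out.nodes
    assert "C" in out.nodes and "D" in out.nodes


def test_hub_removal_cannot_empty_network():
    net = _counted_net({"TREATS": 2})
    with pytest.raises(EmptyNetworkError):
        remove_hub_nodes(net, net.n_nodes)


# ------------------------------------------------------------ support filter
def _support_net(sizes):
    mg_rows = []
    for i, k in enumerate(sizes):
        pm = "|".join(f"p{i}_{j}" for j in range(k))
        mg_rows.append((f"C{i}", "Compound", "TREATS", f"D{i}", "Disease", pm))
    return triples_to_hetnet(triples(mg_rows), ABBREVS)


def test_low_support_filter_threshold():
    net = _support_net([1, 2, 5])
    out = filter_low_support_edges(net, 2)
    assert out.n_edges == 2
    assert filter_low_support_edges(net, 1) == net


def test_low_support_filter_removes_isolated_nodes():
    net = _support_net([1, 3])
    out = filter_low_support_edges(net, 2)
    assert "C0" not in out.nodes and "D0" not in out.nodes
    assert "C1" in out.nodes


# ----------------------------------------------------------------- pipeline
def _pipeline_inputs():
    rows = [
        ("A", "Compound", "TREATS", "B", "Disease", "p1|p2"),
        ("A", "Compound", "PREVENTS", "B", "Disease", "p3"),
        ("A2", "Compound", "TREATS", "C", "Disease", "p4|p5"),
        ("A", "Compound", "CAUSES", "C", "Disease", "p6|p7"),
    ]
    cm = {"A2": ("A", "drug A")}
    cond = {("Compound", "PREVENTS", "Disease"): "TREATS"}
    return triples(rows), cm, cond


def test_full_pipeline_is_deterministic(tmp_path):
    t, cm, cond = _pipeline_inputs()
    outs = []
    for run in ("a", "b"):
        net, _ = build_network(
            t, ABBREVS, concept_map=cm, condense_map=cond,
            sparse_fraction=0.0, hub_top=0, min_support=2,
        )
        paths = write_hetnet(net, tmp_path / run)
        outs.append(
            tuple(p.read_bytes() for p in sorted(paths.values()))
        )
    assert outs[0] == outs[1]


def test_pipeline_never_grows_the_network():
    t, cm, cond = _pipeline_inputs()
    raw = triples_to_hetnet(t, ABBREVS)
    net, report = build_network(
        t, ABBREVS, concept_map=cm, condense_map=cond,
        sparse_fraction=0.0, hub_top=0, min_support=2,
    )
    assert net.n_nodes <= raw.n_nodes and net.n_edges <= raw.n_edges
    # A-TREATS-B carries p1,p2,p3 after remap+condense; A-TREATS-C p4,p5;
    # A-CAUSES-C p6,p7: all survive min_support=2
    assert net.n_edges == 3
    treats_ab = [e for e in net.edges if e.metaedge == "CDtDO" and e.target == "B"]
    assert treats_ab[0].pmids == frozenset({"p1", "p2", "p3"})


def test_triples_to_hetnet_merges_undirected_orientations():
    rows = [
        ("C2", "Compound", "RELATED_TO", "C1", "Compound", "p1"),
        ("C1", "Compound", "RELATED_TO", "C2", "Compound", "p2"),
    ]
    net = triples_to_hetnet(
        triples(rows), ABBREVS, undirected_predicates={"RELATED_TO"}
    )
    (edge,) = net.edges
    assert (edge.source, edge.target) == ("C1", "C2")
    assert edge.pmids == frozenset({"p1", "p2"})
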