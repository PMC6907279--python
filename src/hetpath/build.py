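"""Construction of a cleaned hetnet from a raw triple table.

A raw table holds one subject-predicate-object triple per row together
with a supporting publication id.  Five cleaning rules turn it into a
network suitable for path-based learning, applied in this fixed order:

1. concept remapping (merge granular identifiers into canonical ones),
2. edge-type condensation (merge predicates of similar meaning, e.g.
   PREVENTS into TREATS; drop listed classes),
3. sparse edge-type removal (types carrying < 0.1% of all edges, strict),
4. hub-node removal (top-n nodes by total degree; ties at the cutoff are
   broken by lexicographic node id),
5. low-support edge removal (edges with fewer than 2 supporting
   publication ids), followed by pruning of isolated nodes.

The pipeline is deterministic: identical inputs give byte-identical
serialised outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyNetworkError, SchemaError
from .hetnet import Edge, HetNet, Node
from .metagraph import MetaEdge, Metagraph

#: Sentinel predicate in a condensation map meaning "remove this class".
DROP = "DROP"

#: Edge-token defaults for common predicates; initials are used otherwise.
PREDICATE_TOKENS = {
    "TREATS": "t",
    "RELATED_TO": "rt",
    "ASSOCIATED_WITH": "aw",
    "LOCATION_OF": "lo",
    "AFFECTS": "af",
    "REGULATES": "reg",
    "INTERACTS_WITH": "iw",
    "STIMULATES": "st",
    "INHIBITS": "ib",
    "AUGMENTS": "ag",
    "CAUSES": "c",
    "PREVENTS": "pv",
    "DISRUPTS": "ds",
    "PART_OF": "po",
    "COEXISTS_WITH": "cw",
}

TRIPLE_COLUMNS = [
    "subject",
    "subject_type",
    "predicate",
    "object",
    "object_type",
    "pmids",
]


# ------------------------------------------------------------- triple tables
def read_triples(path, sep: str = "\t") -> pd.DataFrame:
    """Read a triple table; duplicate triples union their publication ids.

    The publication column may hold a single id per row (SemMedDB style)
    or a pipe-joined list.  Rows with an empty publication field are
    rejected with their line numbers.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if list(df.columns[: len(TRIPLE_COLUMNS)]) != TRIPLE_COLUMNS:
        raise SchemaError(
            f"{path}: expected columns {TRIPLE_COLUMNS}, found {list(df.columns)}"
        )
    bad = [
        str(i + 2)  # +2: header line and 1-based numbering
        for i, v in enumerate(df["pmids"])
        if not frozenset(p for p in v.split("|") if p)
    ]
    if bad:
        raise SchemaError(f"{path}: empty publication field on lines {', '.join(bad)}")
    df = df.copy()
    df["pmids"] = [frozenset(p for p in v.split("|") if p) for v in df["pmids"]]
    return _dedupe(df)


def _dedupe(triples: pd.DataFrame) -> pd.DataFrame:
    """Merge identical triples, unioning publication-id sets; sort rows."""
    keys = ["subject", "subject_type", "predicate", "object", "object_type"]
    merged = (
        triples.groupby(keys, sort=True)["pmids"]
        .agg(lambda sets: frozenset().union(*sets))
        .reset_index()
    )
    return merged[TRIPLE_COLUMNS]


def remap_concepts(
    triples: pd.DataFrame, concept_map: Mapping[str, tuple[str, str]]
) -> tuple[pd.DataFrame, dict]:
    """Replace raw concept ids by canonical ids; merge the resulting duplicates.

    Ids absent from the map pass through unchanged (counted in the report).
    Triples whose subject equals their object after mapping are dropped.
    """
    canon = {raw: cid for raw, (cid, _name) in concept_map.items()}
    out = triples.copy()
    n_mapped = int(out["subject"].isin(canon).sum() + out["object"].isin(canon).sum())
    out["subject"] = out["subject"].map(lambda x: canon.get(x, x))
    out["object"] = out["object"].map(lambda x: canon.get(x, x))
    self_rows = out["subject"] == out["object"]
    out = out[~self_rows]
    before = len(out)
    out = _dedupe(out)
    report = {
        "mapped_mentions": n_mapped,
        "dropped_self_triples": int(self_rows.sum()),
        "merged_triples": before - len(out),
    }
    return out, report


def condense_edge_types(
    triples: pd.DataFrame,
    condense_map: Mapping[tuple[str, str, str], str],
) -> tuple[pd.DataFrame, dict]:
    """Rewrite predicates class-by-class; ``DROP`` removes the class entirely."""
    out = triples.copy()
    keys = list(zip(out["subject_type"], out["predicate"], out["object_type"]))
    new_pred = [condense_map.get(k, k[1]) for k in keys]
    out["predicate"] = new_pred
    dropped = out["predicate"] == DROP
    out = out[~dropped]
    before = len(out)
    out = _dedupe(out)
    return out, {
        "dropped_triples": int(dropped.sum()),
        "merged_triples": before - len(out),
    }


def read_condense_map(path) -> dict[tuple[str, str, str], str]:
    """4-column CSV: source type, predicate, target type, replacement (or DROP)."""
    cmap: dict[tuple[str, str, str], str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (lineno == 1 and row[1].lower() == "predicate"):
                continue
            if len(row) != 4:
                raise SchemaError(f"{path}:{lineno}: expected 4 fields")
            cmap[(row[0], row[1], row[2])] = row[3]
    return cmap


def read_concept_map(path, sep: str = "\t") -> dict[str, tuple[str, str]]:
    """3-column table: raw id, canonical id, canonical name."""
    cm: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.lower().startswith("raw")):
                continue
            parts = line.split(sep)
            if len(parts) != 3:
                raise SchemaError(f"{path}:{lineno}: expected 3 fields")
            cm[parts[0]] = (parts[1], parts[2])
    return cm


# --------------------------------------------------- triples -> hetnet bridge
def _token_for(predicate: str, taken: set[str], overrides: Mapping[str, str]) -> str:
    if predicate in overrides:
        return overrides[predicate]
    if predicate in PREDICATE_TOKENS:
        return PREDICATE_TOKENS[predicate]
    initials = "".join(w[0] for w in predicate.lower().split("_") if w)
    token = initials or "x"
    while token in taken:
        token += "x"
    return token


def triples_to_hetnet(
    triples: pd.DataFrame,
    node_type_abbrevs: Mapping[str, str],
    undirected_predicates: Iterable[str] = (),
    names: Mapping[str, str] | None = None,
    predicate_tokens: Mapping[str, str] | None = None,
) -> HetNet:
    """Build a hetnet (and its metagraph) from a cleaned triple table.

    Each observed (subject type, predicate, object type) class becomes a
    metaedge.  Predicates listed in ``undirected_predicates`` become
    undirected when they connect a type to itself; their A-B / B-A triples
    are merged under a canonical endpoint ordering.  Self-referential
    triples are rejected.
    """
    undirected = set(undirected_predicates)
    names = names or {}
    overrides = dict(predicate_tokens or {})

    classes = sorted(
        set(zip(triples["subject_type"], triples["predicate"], triples["object_type"]))
    )
    metaedges = []
    taken_per_pair: dict[frozenset, set[str]] = {}
    for stype, pred, otype in classes:
        pair = frozenset((stype, otype))
        taken = taken_per_pair.setdefault(pair, set())
        token = _token_for(pred, taken, overrides)
        taken.add(token)
        directed = not (pred in undirected and stype == otype)
        metaedges.append(MetaEdge(stype, pred, otype, token, directed))
    mg = Metagraph(dict(node_type_abbrevs), metaedges)
    me_abbrev = {
        (me.source, me.predicate, me.target): mg.abbrev(me) for me in metaedges
    }

    nodes: dict[str, Node] = {}
    merged: dict[tuple[str, str, str], Edge] = {}
    for row in triples.itertuples(index=False):
        if row.subject == row.object:
            raise SchemaError(f"self-referential triple {row.subject!r} rejected")
        for nid, ntype in ((row.subject, row.subject_type), (row.object, row.object_type)):
            known = nodes.get(nid)
            if known is not None and known.type != ntype:
                raise SchemaError(
                    f"concept {nid!r} appears with types {known.type!r} and {ntype!r}"
                )
            nodes[nid] = Node(nid, names.get(nid, nid), ntype)
        ab = me_abbrev[(row.subject_type, row.predicate, row.object_type)]
        me = mg.metaedge(ab)
        s, t = row.subject, row.object
        if not me.directed and s > t:
            s, t = t, s
        key = (s, t, ab)
        old = merged.get(key)
        pmids = row.pmids if old is None else old.pmids | row.pmids
        merged[key] = Edge(s, t, ab, pmids)
    return HetNet(mg, nodes, merged.values(), validate=True)


# ------------------------------------------------------------ network filters
def filter_sparse_edge_types(net: HetNet, min_fraction: float = 0.001) -> HetNet:
    """Remove metaedges carrying strictly less than ``min_fraction`` of edges."""
    if not 0 <= min_fraction < 1:
        raise SchemaError("min_fraction must be in [0, 1)")
    total = net.n_edges
    if total == 0:
        raise EmptyNetworkError("network has no edges")
    keep = [
        me
        for me in net.metagraph.metaedges
        if not len(net.edges_of(net.metagraph.abbrev(me))) / total < min_fraction
    ]
    if not keep:
        raise EmptyNetworkError("sparse-type filter would remove every metaedge")
    if len(keep) == len(net.metagraph.metaedges):
        return net
    return net.with_metagraph(Metagraph(net.metagraph.node_types, keep))


def remove_hub_nodes(net: HetNet, n_top: int = 100) -> HetNet:
    """Delete the ``n_top`` highest-total-degree nodes and their edges.

    Total degree is the incident edge count across all metaedges at both
    ends.  Ties at the cutoff are broken by lexicographic node id.
    """
    if n_top < 0:
        raise SchemaError("n_top must be >= 0")
    if n_top == 0:
        return net
    if n_top >= net.n_nodes:
        raise EmptyNetworkError(f"removing {n_top} hubs would empty the network")
    totals = {nid: 0 for nid in net.nodes}
    for e in net.edges:
        totals[e.source] += 1
        totals[e.target] += 1
    ranked = sorted(totals, key=lambda nid: (-totals[nid], nid))
    hubs = set(ranked[:n_top])
    keep_nodes = {nid: n for nid, n in net.nodes.items() if nid not in hubs}
    return HetNet(
        net.metagraph,
        keep_nodes,
        (e for e in net.edges if e.source not in hubs and e.target not in hubs),
        validate=False,
    )


def filter_low_support_edges(net: HetNet, min_pmids: int = 2) -> HetNet:
    """Keep edges with at least ``min_pmids`` supporting publication ids.

    Nodes left without any edge are removed as well.
    """
    if min_pmids < 1:
        raise SchemaError("min_pmids must be >= 1")
    if min_pmids == 1:
        return net
    return net.filter_edges(lambda e: len(e.pmids) >= min_pmids).drop_isolated_nodes()


@dataclass
class BuildReport:
    remap: dict = field(default_factory=dict)
    condense: dict = field(default_factory=dict)
    n_triples: int = 0
    n_nodes: int = 0
    n_edges: int = 0


def build_network(
    triples: pd.DataFrame,
    node_type_abbrevs: Mapping[str, str],
    concept_map: Mapping[str, tuple[str, str]] | None = None,
    condense_map: Mapping[tuple[str, str, str], str] | None = None,
    undirected_predicates: Iterable[str] = (),
    sparse_fraction: float = 0.001,
    hub_top: int = 100,
    min_support: int = 2,
    predicate_tokens: Mapping[str, str] | None = None,
) -> tuple[HetNet, BuildReport]:
    """Full cleaning pipeline: remap → condense → sparse → hubs → support."""
    report = BuildReport()
    names = None
    if concept_map:
        triples, report.remap = remap_concepts(triples, concept_map)
        names = {cid: name for cid, name in concept_map.values()}
    if condense_map:
        triples, report.condense = condense_edge_types(triples, condense_map)
    report.n_triples = len(triples)
    net = triples_to_hetnet(
        triples,
        node_type_abbrevs,
        undirected_predicates,
        names=names,
        predicate_tokens=predicate_tokens,
    )
    net = filter_sparse_edge_types(net, sparse_fraction)
    net = remove_hub_nodes(net, hub_top)
    net = filter_low_support_edges(net, min_support)
    report.n_nodes = net.n_nodes
    report.n_edges = net.n_edges
    return net, report
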