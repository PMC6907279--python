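"""Table I/O for hetnets.

Nodes and edges travel as UTF-8 TSV with headers; the metagraph travels as
a YAML config file.  ``write_hetnet`` then ``read_hetnet`` round-trips to an
equal network: rows are emitted in a canonical sort order and PMID sets are
pipe-joined sorted, so re-serialisation is byte-identical.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

from .errors import ReferentialIntegrityError, SchemaError
from .hetnet import Edge, HetNet, Node
from .metagraph import Metagraph

NODE_COLUMNS = ["id", "name", "type"]
EDGE_COLUMNS = ["source", "target", "metaedge", "pmids", "year"]


def _read_rows(path, expected_columns):
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        if header[: len(expected_columns)] != expected_columns:
            raise SchemaError(
                f"{path}: expected header {expected_columns}, found {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            yield lineno, row


def read_hetnet(node_table_path, edge_table_path, metagraph) -> HetNet:
    """Load a hetnet from node/edge TSVs plus a metagraph (object or YAML path).

    Malformed rows are collected and reported with their line numbers; an
    edge referencing an absent node raises :class:`ReferentialIntegrityError`,
    any other violation raises :class:`SchemaError`.
    """
    if not isinstance(metagraph, Metagraph):
        metagraph = Metagraph.from_yaml(metagraph)

    schema_errors: list[str] = []
    ref_errors: list[str] = []

    nodes: dict[str, Node] = {}
    for lineno, row in _read_rows(node_table_path, NODE_COLUMNS):
        if len(row) != 3:
            schema_errors.append(f"{node_table_path}:{lineno}: expected 3 fields")
            continue
        nid, name, ntype = row
        if ntype not in metagraph.node_types:
            schema_errors.append(
                f"{node_table_path}:{lineno}: unknown node type {ntype!r}"
            )
            continue
        if nid in nodes:
            schema_errors.append(f"{node_table_path}:{lineno}: duplicate node id {nid!r}")
            continue
        nodes[nid] = Node(nid, name, ntype)

    edges: list[Edge] = []
    for lineno, row in _read_rows(edge_table_path, EDGE_COLUMNS):
        if len(row) not in (4, 5):
            schema_errors.append(f"{edge_table_path}:{lineno}: expected 4-5 fields")
            continue
        source, target, ab = row[0], row[1], row[2]
        pmids = frozenset(p for p in row[3].split("|") if p)
        year_field = row[4].strip() if len(row) == 5 else ""
        year = None
        if year_field:
            try:
                year = int(year_field)
            except ValueError:
                schema_errors.append(
                    f"{edge_table_path}:{lineno}: invalid year {year_field!r}"
                )
                continue
        if ab not in metagraph.metaedge_abbrevs:
            schema_errors.append(f"{edge_table_path}:{lineno}: unknown metaedge {ab!r}")
            continue
        me = metagraph.metaedge(ab)
        bad = False
        for nid, want in ((source, me.source), (target, me.target)):
            node = nodes.get(nid)
            if node is None:
                ref_errors.append(
                    f"{edge_table_path}:{lineno}: edge references missing node {nid!r}"
                )
                bad = True
            elif node.type != want:
                schema_errors.append(
                    f"{edge_table_path}:{lineno}: node {nid!r} has type "
                    f"{node.type!r}, metaedge {ab} expects {want!r}"
                )
                bad = True
        if bad:
            continue
        edges.append(Edge(source, target, ab, pmids, year))

    if schema_errors:
        raise SchemaError("\n".join(schema_errors + ref_errors))
    if ref_errors:
        raise ReferentialIntegrityError("\n".join(ref_errors))
    return HetNet(metagraph, nodes, edges, validate=True)


def write_hetnet(net: HetNet, out_dir) -> dict[str, Path]:
    """Write ``nodes.tsv``, ``edges.tsv`` and ``metagraph.yml`` into ``out_dir``."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "nodes": out_dir / "nodes.tsv",
        "edges": out_dir / "edges.tsv",
        "metagraph": out_dir / "metagraph.yml",
    }
    with open(paths["nodes"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(NODE_COLUMNS)
        for nid in sorted(net.nodes):
            n = net.nodes[nid]
            w.writerow([n.id, n.name, n.type])
    with open(paths["edges"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EDGE_COLUMNS)
        for e in sorted(net.edges, key=lambda e: (e.metaedge, e.source, e.target)):
            w.writerow(
                [
                    e.source,
                    e.target,
                    e.metaedge,
                    "|".join(sorted(e.pmids)),
                    "" if e.year is None else e.year,
                ]
            )
    net.metagraph.to_yaml(paths["metagraph"])
    return paths


def read_year_map(path) -> dict[str, int]:
    """Two-column TSV mapping publication id to a 4-digit year."""
    ym: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.lower().startswith("pmid")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{path}:{lineno}: expected 2 fields")
            ym[parts[0]] = int(parts[1])
    return ym


def write_year_map(year_map: dict[str, int], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("pmid\tyear\n")
        for pmid in sorted(year_map):
            fh.write(f"{pmid}\t{year_map[pmid]}\n")
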