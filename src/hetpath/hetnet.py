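"""Hetnet instance layer: typed nodes and provenance-carrying edges.

Every edge records the set of supporting publication identifiers (PMIDs in
the text-mining setting) and, once dated, the earliest publication year of
that set.  ``HetNet`` objects are treated as immutable: all transformations
return new instances, so degree tables and node orderings can be cached
safely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping

from .errors import IdentifierError, ReferentialIntegrityError, SchemaError
from .metagraph import MetaEdge, Metagraph


@dataclass(frozen=True)
class Node:
    id: str
    name: str
    type: str


@dataclass(frozen=True)
class Edge:
    """One edge instance; ``metaedge`` is the full metaedge abbreviation."""

    source: str
    target: str
    metaedge: str
    pmids: frozenset = frozenset()
    year: int | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.metaedge)


def _canonical(edge: Edge, me: MetaEdge) -> Edge:
    """Undirected edges are stored once, endpoints in lexicographic order."""
    if not me.directed and edge.source > edge.target:
        return replace(edge, source=edge.target, target=edge.source)
    return edge


class HetNet:
    """A heterogeneous network instance bound to a metagraph."""

    def __init__(
        self,
        metagraph: Metagraph,
        nodes: Iterable[Node] | Mapping[str, Node],
        edges: Iterable[Edge],
        validate: bool = True,
    ):
        self.metagraph = metagraph
        if isinstance(nodes, Mapping):
            self.nodes: dict[str, Node] = dict(nodes)
        else:
            self.nodes = {n.id: n for n in nodes}

        canon: dict[tuple[str, str, str], Edge] = {}
        for e in edges:
            if validate:
                me = metagraph.metaedge(e.metaedge)  # raises IdentifierError
                if e.source == e.target:
                    raise SchemaError(f"self-loop rejected: {e.key}")
                for nid, want in ((e.source, me.source), (e.target, me.target)):
                    node = self.nodes.get(nid)
                    if node is None:
                        raise ReferentialIntegrityError(
                            f"edge {e.key} references missing node {nid!r}"
                        )
                    if node.type != want:
                        raise SchemaError(
                            f"edge {e.key}: node {nid!r} has type {node.type!r}, "
                            f"metaedge expects {want!r}"
                        )
                e = _canonical(e, me)
                if e.key in canon:
                    raise SchemaError(f"duplicate edge {e.key}")
            canon[e.key] = e
        self.edges: tuple[Edge, ...] = tuple(
            canon[k] for k in sorted(canon)
        )

        self._by_metaedge: dict[str, tuple[Edge, ...]] | None = None
        self._degrees: dict[str, tuple[Counter, Counter]] = {}
        self._node_ids: dict[str, tuple[str, ...]] = {}

    # ------------------------------------------------------------- basic views
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self, node_type: str) -> tuple[str, ...]:
        """Sorted node ids of one type; fixed ordering shared by all matrices."""
        if node_type not in self.metagraph.node_types:
            raise IdentifierError(f"unknown node type {node_type!r}")
        if node_type not in self._node_ids:
            self._node_ids[node_type] = tuple(
                sorted(nid for nid, n in self.nodes.items() if n.type == node_type)
            )
        return self._node_ids[node_type]

    def edges_of(self, metaedge_abbrev: str) -> tuple[Edge, ...]:
        self.metagraph.metaedge(metaedge_abbrev)
        if self._by_metaedge is None:
            by: dict[str, list[Edge]] = {}
            for e in self.edges:
                by.setdefault(e.metaedge, []).append(e)
            self._by_metaedge = {k: tuple(v) for k, v in by.items()}
        return self._by_metaedge.get(metaedge_abbrev, ())

    # ---------------------------------------------------------------- degrees
    def _degree_tables(self, abbrev: str) -> tuple[Counter, Counter]:
        if abbrev not in self._degrees:
            me = self.metagraph.metaedge(abbrev)
            edges = self.edges_of(abbrev)
            if me.directed:
                src = Counter(e.source for e in edges)
                tgt = Counter(e.target for e in edges)
            else:
                src = Counter()
                for e in edges:
                    src[e.source] += 1
                    src[e.target] += 1
                tgt = src
            self._degrees[abbrev] = (src, tgt)
        return self._degrees[abbrev]

    def degree(self, node: str, metaedge_abbrev: str, end: str = "source") -> int:
        """Number of ``metaedge`` edges incident to ``node`` at ``end``.

        For undirected metaedges incidences at either end are counted.
        """
        if end not in ("source", "target"):
            raise ValueError("end must be 'source' or 'target'")
        me = self.metagraph.metaedge(metaedge_abbrev)
        n = self.nodes.get(node)
        if n is None:
            raise IdentifierError(f"unknown node {node!r}")
        want = me.source if end == "source" else me.target
        if n.type != want:
            raise IdentifierError(
                f"node {node!r} has type {n.type!r}; the {end} end of "
                f"{metaedge_abbrev} is {want!r}"
            )
        src, tgt = self._degree_tables(metaedge_abbrev)
        table = src if end == "source" else tgt
        return table.get(node, 0)

    # --------------------------------------------------------- transformations
    def filter_edges(self, keep: Callable[[Edge], bool]) -> "HetNet":
        """New net with the same nodes, keeping edges where ``keep`` is true."""
        return HetNet(
            self.metagraph,
            self.nodes,
            (e for e in self.edges if keep(e)),
            validate=False,
        )

    def without_pair_edges(
        self, metaedge_abbrev: str, pairs: Iterable[tuple[str, str]]
    ) -> "HetNet":
        """Drop the given (source, target) edges of one metaedge (if present)."""
        drop = set(pairs)
        return self.filter_edges(
            lambda e: not (e.metaedge == metaedge_abbrev and (e.source, e.target) in drop)
        )

    def with_edges(self, new_edges: Iterable[Edge]) -> "HetNet":
        """Merge edges in: duplicates union their PMID sets, years take the min."""
        merged = {e.key: e for e in self.edges}
        for e in new_edges:
            me = self.metagraph.metaedge(e.metaedge)
            if e.source == e.target:
                raise SchemaError(f"self-loop rejected: {e.key}")
            e = _canonical(e, me)
            old = merged.get(e.key)
            if old is not None:
                years = [y for y in (old.year, e.year) if y is not None]
                e = replace(
                    e,
                    pmids=old.pmids | e.pmids,
                    year=min(years) if years else None,
                )
            merged[e.key] = e
        return HetNet(self.metagraph, self.nodes, merged.values(), validate=True)

    def drop_isolated_nodes(self) -> "HetNet":
        used: set[str] = set()
        for e in self.edges:
            used.add(e.source)
            used.add(e.target)
        keep = {nid: n for nid, n in self.nodes.items() if nid in used}
        return HetNet(self.metagraph, keep, self.edges, validate=False)

    def with_metagraph(self, mg: Metagraph) -> "HetNet":
        keep = set(mg.metaedge_abbrevs)
        return HetNet(
            mg, self.nodes, (e for e in self.edges if e.metaedge in keep), validate=False
        )

    # ------------------------------------------------------------------ dunder
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HetNet):
            return NotImplemented
        return (
            self.metagraph == other.metagraph
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return f"HetNet({self.n_nodes} nodes, {self.n_edges} edges)"


def degree(net: HetNet, node: str, metaedge_abbrev: str, end: str = "source") -> int:
    """Module-level alias for :meth:`HetNet.degree`."""
    return net.degree(node, metaedge_abbrev, end)
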