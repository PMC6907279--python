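"""Hetnet schema layer: node types, metaedges, and metapaths.

A *metagraph* declares the node types of a heterogeneous network together
with its typed edge classes (*metaedges*).  Each node type carries an
upper-case abbreviation (e.g. ``Compound`` -> ``CD``) and each metaedge a
lower-case token (``TREATS`` -> ``t``); concatenating them yields the
compact labels used throughout the package, e.g. ``CDtDO`` for the
Compound-TREATS-Disease metaedge and ``CDrtCDtDO`` for the length-two
metapath "compound related to a compound that treats the disease".

A *metapath* is an ordered chain of metaedge traversals from a source node
type to a target node type.  Directed metaedges may be traversed against
their arrow (a distinct step direction); for a directed metaedge between a
type and itself the label disambiguates the sense with ``>``/``<`` markers
(``CDreg>CD`` forward, ``CD<regCD`` backward).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import yaml

from .errors import IdentifierError, SchemaError

_LABEL_TOKEN = re.compile(r"[A-Z]+|<?[a-z_]+>?")
_EDGE_TOKEN = re.compile(r"[a-z_]+")


@dataclass(frozen=True)
class MetaEdge:
    """A typed edge class: (source type, predicate, target type).

    ``token`` is the lower-case label fragment used in metapath labels.
    Undirected metaedges are only permitted between a type and itself
    (e.g. a symmetric RELATED_TO between compounds).
    """

    source: str
    predicate: str
    target: str
    token: str
    directed: bool = True


class Metagraph:
    """Node types plus metaedges, with label construction and lookup."""

    def __init__(self, node_types: dict[str, str], metaedges: Iterable[MetaEdge]):
        self.node_types = dict(node_types)
        abbrevs = list(self.node_types.values())
        if len(set(abbrevs)) != len(abbrevs):
            raise SchemaError("node-type abbreviations must be unique")
        for ab in abbrevs:
            if not re.fullmatch(r"[A-Z]+", ab):
                raise SchemaError(f"node-type abbreviation {ab!r} must be upper-case letters")
        self._type_of_abbrev = {ab: t for t, ab in self.node_types.items()}

        self.metaedges: tuple[MetaEdge, ...] = tuple(metaedges)
        self._by_abbrev: dict[str, MetaEdge] = {}
        self._by_pair_token: dict[tuple[frozenset, str], MetaEdge] = {}
        for me in self.metaedges:
            if me.source not in self.node_types or me.target not in self.node_types:
                raise SchemaError(f"metaedge {me.predicate} has undeclared endpoint type")
            if not _EDGE_TOKEN.fullmatch(me.token):
                raise SchemaError(f"metaedge token {me.token!r} must be lower-case letters")
            if not me.directed and me.source != me.target:
                raise SchemaError(
                    "undirected metaedges are only supported between a type and itself"
                )
            ab = self.abbrev(me)
            if ab in self._by_abbrev:
                raise SchemaError(f"duplicate metaedge abbreviation {ab!r}")
            self._by_abbrev[ab] = me
            key = (frozenset((me.source, me.target)), me.token)
            if key in self._by_pair_token:
                raise SchemaError(
                    f"token {me.token!r} is ambiguous between types "
                    f"{me.source!r} and {me.target!r}"
                )
            self._by_pair_token[key] = me

    # ------------------------------------------------------------------ labels
    def abbrev(self, me: MetaEdge) -> str:
        """Full metaedge label, e.g. ``CDtDO`` or ``CDreg>CD``."""
        na = self.node_types
        marker = ">" if me.directed and me.source == me.target else ""
        return f"{na[me.source]}{me.token}{marker}{na[me.target]}"

    @property
    def metaedge_abbrevs(self) -> tuple[str, ...]:
        return tuple(self._by_abbrev)

    def metaedge(self, abbrev: str) -> MetaEdge:
        try:
            return self._by_abbrev[abbrev]
        except KeyError:
            raise IdentifierError(f"unknown metaedge {abbrev!r}") from None

    def node_abbrev(self, node_type: str) -> str:
        try:
            return self.node_types[node_type]
        except KeyError:
            raise IdentifierError(f"unknown node type {node_type!r}") from None

    def type_for(self, abbrev: str) -> str:
        try:
            return self._type_of_abbrev[abbrev]
        except KeyError:
            raise IdentifierError(f"unknown node-type abbreviation {abbrev!r}") from None

    # ------------------------------------------------------------------- dunder
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Metagraph):
            return NotImplemented
        return self.node_types == other.node_types and set(self.metaedges) == set(
            other.metaedges
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.node_types.items()), frozenset(self.metaedges)))

    def __repr__(self) -> str:
        return (
            f"Metagraph({len(self.node_types)} node types, "
            f"{len(self.metaedges)} metaedges)"
        )

    # --------------------------------------------------------------------- I/O
    def to_yaml(self, path) -> None:
        doc = {
            "node_types": self.node_types,
            "metaedges": [
                {
                    "source": me.source,
                    "predicate": me.predicate,
                    "target": me.target,
                    "token": me.token,
                    "directed": me.directed,
                }
                for me in self.metaedges
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Metagraph":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        try:
            metaedges = [MetaEdge(**m) for m in doc["metaedges"]]
            return cls(doc["node_types"], metaedges)
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed metagraph file {path}: {exc}") from exc


@dataclass(frozen=True)
class Step:
    """One metapath step: a metaedge plus the traversal sense."""

    metaedge: MetaEdge
    forward: bool = True

    @property
    def start_type(self) -> str:
        return self.metaedge.source if self.forward else self.metaedge.target

    @property
    def end_type(self) -> str:
        return self.metaedge.target if self.forward else self.metaedge.source


class Metapath:
    """An ordered chain of steps from a source node type to a target type."""

    __slots__ = ("metagraph", "steps")

    def __init__(self, metagraph: Metagraph, steps: Sequence[Step]):
        steps = tuple(steps)
        if not steps:
            raise SchemaError("a metapath must contain at least one step")
        for a, b in zip(steps, steps[1:]):
            if a.end_type != b.start_type:
                raise SchemaError(
                    f"metapath steps do not chain: {a.end_type!r} != {b.start_type!r}"
                )
        self.metagraph = metagraph
        self.steps = steps

    @property
    def source_type(self) -> str:
        return self.steps[0].start_type

    @property
    def target_type(self) -> str:
        return self.steps[-1].end_type

    @property
    def node_types_along(self) -> tuple[str, ...]:
        return (self.source_type,) + tuple(s.end_type for s in self.steps)

    @property
    def label(self) -> str:
        na = self.metagraph.node_types
        parts = [na[self.source_type]]
        for st in self.steps:
            me = st.metaedge
            tok = me.token
            if me.directed and me.source == me.target:
                tok = tok + ">" if st.forward else "<" + tok
            parts.append(tok)
            parts.append(na[st.end_type])
        return "".join(parts)

    def __len__(self) -> int:
        return len(self.steps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Metapath):
            return NotImplemented
        return self.steps == other.steps

    def __hash__(self) -> int:
        return hash(self.steps)

    def __repr__(self) -> str:
        return f"Metapath({self.label})"

    @classmethod
    def parse(cls, metagraph: Metagraph, label: str) -> "Metapath":
        """Inverse of :attr:`label` (requires the metagraph for typing)."""
        tokens = _LABEL_TOKEN.findall(label)
        if "".join(tokens) != label or len(tokens) < 3 or len(tokens) % 2 == 0:
            raise SchemaError(f"malformed metapath label {label!r}")
        types = []
        for tok in tokens[::2]:
            types.append(metagraph.type_for(tok))
        steps = []
        for i, tok in enumerate(tokens[1::2]):
            tx, ty = types[i], types[i + 1]
            if tok.startswith("<") or tok.endswith(">"):
                forward = tok.endswith(">")
                bare = tok.strip("<>")
                me = metagraph._by_pair_token.get((frozenset((tx, ty)), bare))
                if me is None or not me.directed or me.source != me.target:
                    raise SchemaError(f"no same-type directed metaedge for {tok!r} in {label!r}")
            else:
                me = metagraph._by_pair_token.get((frozenset((tx, ty)), tok))
                if me is None:
                    raise SchemaError(
                        f"no metaedge {tok!r} between {tx!r} and {ty!r} in {label!r}"
                    )
                if me.directed and me.source == me.target:
                    raise SchemaError(f"label {label!r} omits direction marker for {tok!r}")
                forward = me.source == tx if tx != ty else True
                if me.source == tx and me.target != ty:
                    raise SchemaError(f"metaedge {tok!r} does not reach {ty!r}")
            steps.append(Step(me, forward))
        return cls(metagraph, steps)


def _steps_from(
    mg: Metagraph, node_type: str, excluded_reverse: frozenset[MetaEdge]
) -> Iterator[Step]:
    for me in mg.metaedges:
        if me.source == node_type:
            yield Step(me, True)
        if (
            me.target == node_type
            and me.directed
            and me not in excluded_reverse
        ):
            yield Step(me, False)


def enumerate_metapaths(
    mg: Metagraph,
    source_type: str,
    target_type: str,
    max_length: int,
    exclude_reverse: object = "auto",
) -> list[Metapath]:
    """All metapaths from ``source_type`` to ``target_type`` up to ``max_length``.

    Undirected metaedges are traversed freely; directed metaedges may be
    traversed forward or backward (distinct step directions).  By default
    (``exclude_reverse="auto"``) directed metaedges leading straight from the
    source type to the target type — the relation being predicted, e.g.
    TREATS for compound→disease features — are never traversed in reverse.
    Pass an iterable of metaedge abbreviations to exclude explicitly, or
    ``()`` / ``None`` for unrestricted traversal.

    Results are deterministic: sorted by length, then label.
    """
    if max_length < 1:
        raise SchemaError("max_length must be >= 1")
    for t in (source_type, target_type):
        if t not in mg.node_types:
            raise IdentifierError(f"unknown node type {t!r}")
    if exclude_reverse == "auto":
        excluded = frozenset(
            me
            for me in mg.metaedges
            if me.directed and me.source == source_type and me.target == target_type
        )
    elif not exclude_reverse:
        excluded = frozenset()
    else:
        excluded = frozenset(mg.metaedge(ab) for ab in exclude_reverse)

    found: list[Metapath] = []

    def extend(current_type: str, prefix: tuple[Step, ...]) -> None:
        if len(prefix) >= max_length:
            return
        for step in _steps_from(mg, current_type, excluded):
            chain = prefix + (step,)
            if step.end_type == target_type:
                found.append(Metapath(mg, chain))
            extend(step.end_type, chain)

    extend(source_type, ())
    found.sort(key=lambda mp: (len(mp), mp.label))
    return found
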