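"""Degree-weighted path counts (DWPC) via sparse adjacency-matrix products.

The DWPC of a metapath ``m`` between a source node ``s`` and target ``t``
is the sum over node-distinct paths conforming to ``m`` of the product,
over path edges, of ``(d_u * d_v) ** -w`` where ``d_u``/``d_v`` are the
endpoints' degrees with respect to that edge's metaedge and ``w >= 0`` is
the damping exponent.  ``w = 0`` recovers plain node-distinct path counts;
larger ``w`` down-weights paths through hub nodes.

Chained products of degree-weighted adjacency matrices count *walks*; the
matrix engine subtracts the walk contributions that revisit a node, which
is exact for metapaths of length <= 3 (repeats can only occur between
positions of equal node type, and adjacent repeats are impossible because
self-loops are rejected at load time).  Longer metapaths fall back to the
exhaustive per-pair oracle.  The oracle itself is a depth-first path
enumeration and is the governing reference for correctness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import BudgetError, IdentifierError, SchemaError
from .hetnet import HetNet
from .metagraph import Metapath, Step, enumerate_metapaths


@dataclass(frozen=True)
class FeatureConfig:
    """Settings for drug→disease feature extraction.

    ``w`` is the damping exponent (0 turns damping off); ``max_length``
    bounds metapath length.  The defaults (w=0.4, length 3) are the
    package's standard operating point.
    """

    source_type: str
    target_type: str
    w: float = 0.4
    max_length: int = 3
    exclude_reverse: object = "auto"

    def __post_init__(self):
        if self.w < 0:
            raise SchemaError("damping exponent w must be >= 0")
        if self.max_length < 1:
            raise SchemaError("max_length must be >= 1")

    def metapaths(self, net: HetNet) -> list[Metapath]:
        return enumerate_metapaths(
            net.metagraph,
            self.source_type,
            self.target_type,
            self.max_length,
            self.exclude_reverse,
        )


# --------------------------------------------------------------------- engine
def weighted_adjacency(
    net: HetNet, metaedge_abbrev: str, direction: str = "forward", w: float = 0.4
) -> sp.csr_matrix:
    """Degree-weighted adjacency for one metaedge traversal.

    Rows index the traversal's start-type nodes, columns its end-type nodes
    (both in the net's canonical sorted order).  Entry (u, v) is
    ``(d_u * d_v) ** -w`` if the edge exists, else 0; degree-zero nodes
    yield all-zero rows/columns (0**-w is never evaluated because an
    existing edge implies both endpoint degrees are >= 1).
    """
    me = net.metagraph.metaedge(metaedge_abbrev)
    forward = direction in ("forward", True)
    return _step_matrix(net, Step(me, forward), w)


def _step_matrix(net: HetNet, step: Step, w: float) -> sp.csr_matrix:
    me = step.metaedge
    ab = net.metagraph.abbrev(me)
    rows_ids = net.node_ids(step.start_type)
    cols_ids = net.node_ids(step.end_type)
    ridx = {n: i for i, n in enumerate(rows_ids)}
    cidx = {n: i for i, n in enumerate(cols_ids)}
    src_deg, tgt_deg = net._degree_tables(ab)

    rows, cols, vals = [], [], []

    def emit(u, v):
        # u sits at the metaedge's source end, v at its target end
        weight = 1.0 if w == 0 else float(src_deg[u] * tgt_deg[v]) ** (-w)
        if step.forward:
            rows.append(ridx[u])
            cols.append(cidx[v])
        else:
            rows.append(ridx[v])
            cols.append(cidx[u])
        vals.append(weight)

    for e in net.edges_of(ab):
        emit(e.source, e.target)
        if not me.directed:
            emit(e.target, e.source)

    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(rows_ids), len(cols_ids))
    )


def _product_diagonal(a: sp.spmatrix, b: sp.spmatrix) -> np.ndarray:
    """diag(a @ b) without forming the product."""
    return np.asarray(a.multiply(b.T).sum(axis=1)).ravel()


def _zero_diagonal(m: sp.csr_matrix) -> sp.csr_matrix:
    d = m.diagonal()
    if np.any(d):
        m = (m - sp.diags(d)).tocsr()
    return m


def dwpc_matrix(net: HetNet, mp: Metapath, w: float = 0.4) -> sp.csr_matrix:
    """DWPC for all (source, target) node pairs of a metapath.

    Exact node-distinct semantics for length <= 3 via walk-count
    corrections; longer metapaths are evaluated with the oracle per pair.
    """
    if mp.metagraph != net.metagraph:
        raise SchemaError("metapath and network use different metagraphs")
    if len(mp) > 3:
        return _oracle_matrix(net, mp, w)
    mats = [_step_matrix(net, st, w) for st in mp.steps]
    types = mp.node_types_along

    if len(mp) == 1:
        result = mats[0].copy()
        if types[0] == types[1]:
            result = _zero_diagonal(result.tocsr())
        return result.tocsr()

    if len(mp) == 2:
        result = (mats[0] @ mats[1]).tocsr()
        if types[0] == types[2]:
            result = _zero_diagonal(result)
        return result

    a, b, c = mats
    result = (a @ b @ c).tocsr()
    # subtract walks revisiting a node: only positions of equal type can repeat
    if types[0] == types[2]:
        result = (result - sp.diags(_product_diagonal(a, b)) @ c).tocsr()
    if types[1] == types[3]:
        result = (result - a @ sp.diags(_product_diagonal(b, c))).tocsr()
    if types[0] == types[2] and types[1] == types[3]:
        # walks with v0==v2 and v1==v3 were subtracted twice; add back once
        result = (result + a.multiply(b.T).multiply(c)).tocsr()
    if types[0] == types[3]:
        result = _zero_diagonal(result)
    result.eliminate_zeros()
    return result


def _oracle_matrix(net: HetNet, mp: Metapath, w: float) -> sp.csr_matrix:
    srcs = net.node_ids(mp.source_type)
    tgts = net.node_ids(mp.target_type)
    out = np.zeros((len(srcs), len(tgts)))
    for i, s in enumerate(srcs):
        for j, t in enumerate(tgts):
            out[i, j] = dwpc_oracle(net, s, t, mp, w)
    return sp.csr_matrix(out)


# --------------------------------------------------------------------- oracle
def dwpc_oracle(
    net: HetNet,
    source: str,
    target: str,
    mp: Metapath,
    w: float = 0.4,
    max_paths: int = 10_000,
) -> float:
    """Exact DWPC by depth-first enumeration of node-distinct paths.

    Independent of the matrix engine; guarded by ``max_paths`` on the
    number of partial path extensions explored.
    """
    for nid, want in ((source, mp.source_type), (target, mp.target_type)):
        node = net.nodes.get(nid)
        if node is None or node.type != want:
            raise IdentifierError(f"node {nid!r} missing or not of type {want!r}")

    # per-step adjacency with per-edge weights, built from raw edges
    step_adj: list[dict[str, list[tuple[str, float]]]] = []
    for st in mp.steps:
        me = st.metaedge
        ab = net.metagraph.abbrev(me)
        src_deg, tgt_deg = net._degree_tables(ab)
        adj: dict[str, list[tuple[str, float]]] = {}
        for e in net.edges_of(ab):
            weight = 1.0 if w == 0 else float(src_deg[e.source] * tgt_deg[e.target]) ** (-w)
            if st.forward or not me.directed:
                adj.setdefault(e.source, []).append((e.target, weight))
            if (not st.forward) or not me.directed:
                adj.setdefault(e.target, []).append((e.source, weight))
        step_adj.append(adj)

    total = 0.0
    explored = 0

    def recurse(node: str, depth: int, visited: frozenset, prod: float) -> None:
        nonlocal total, explored
        if depth == len(mp):
            if node == target:
                total += prod
            return
        for nxt, weight in step_adj[depth].get(node, ()):
            if nxt in visited:
                continue
            explored += 1
            if explored > max_paths:
                raise BudgetError(f"oracle path budget exceeded ({max_paths})")
            recurse(nxt, depth + 1, visited | {nxt}, prod * weight)

    recurse(source, 0, frozenset({source}), 1.0)
    return total


# ------------------------------------------------------------------- features
def _degree_column_spec(net: HetNet, node_type: str) -> list[tuple[str, str, str]]:
    """(column suffix, metaedge abbrev, end) for every degree feature of a type."""
    spec = []
    for ab in sorted(net.metagraph.metaedge_abbrevs):
        me = net.metagraph.metaedge(ab)
        if me.source == me.target == node_type:
            if me.directed:
                spec.append((f"{ab}_out", ab, "source"))
                spec.append((f"{ab}_in", ab, "target"))
            else:
                spec.append((ab, ab, "source"))
        elif me.source == node_type:
            spec.append((ab, ab, "source"))
        elif me.target == node_type:
            spec.append((ab, ab, "target"))
    return spec


def extract_features(
    net: HetNet,
    pairs: Sequence[tuple[str, str]],
    cfg: FeatureConfig,
) -> pd.DataFrame:
    """DWPC plus degree features for (source, target) node pairs.

    Returns a DataFrame indexed by (source, target) with one ``dwpc_<label>``
    column per metapath and ``degree_source_<metaedge>`` /
    ``degree_target_<metaedge>`` count columns for the pair's endpoints.
    Column order is deterministic: metapaths by (length, label), then degree
    columns sorted by metaedge.
    """
    pairs = list(pairs)
    missing = [
        p
        for p in pairs
        if net.nodes.get(p[0]) is None
        or net.nodes.get(p[1]) is None
        or net.nodes[p[0]].type != cfg.source_type
        or net.nodes[p[1]].type != cfg.target_type
    ]
    if missing:
        raise IdentifierError(f"pairs with missing or mistyped endpoints: {missing}")

    src_ids = net.node_ids(cfg.source_type)
    tgt_ids = net.node_ids(cfg.target_type)
    sidx = {n: i for i, n in enumerate(src_ids)}
    tidx = {n: i for i, n in enumerate(tgt_ids)}
    ri = np.fromiter((sidx[p[0]] for p in pairs), dtype=int, count=len(pairs))
    ci = np.fromiter((tidx[p[1]] for p in pairs), dtype=int, count=len(pairs))

    data: dict[str, np.ndarray] = {}
    for mp in cfg.metapaths(net):
        m = dwpc_matrix(net, mp, cfg.w).toarray()
        data[f"dwpc_{mp.label}"] = m[ri, ci] if len(pairs) else np.empty(0)

    for role, ntype, idx in (
        ("source", cfg.source_type, 0),
        ("target", cfg.target_type, 1),
    ):
        for suffix, ab, end in _degree_column_spec(net, ntype):
            col = f"degree_{role}_{suffix}"
            data[col] = np.fromiter(
                (net.degree(p[idx], ab, end) for p in pairs),
                dtype=int,
                count=len(pairs),
            )

    index = pd.MultiIndex.from_tuples(pairs, names=["source", "target"])
    return pd.DataFrame(data, index=index)
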