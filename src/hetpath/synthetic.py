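"""Synthetic dated hetnets with planted, recoverable repositioning signal.

The generator emulates the structure a text-mined biomedical network
presents to the learning pipeline, at desk scale:

* four node types (Compound, Disease, Gene, Anatomy) and seven metaedges,
  including TREATS-, RELATED_TO- and ASSOCIATED_WITH-analogues;
* every edge carries a set of synthetic publication ids and an earliest
  year; the per-year edge-arrival rate grows exponentially, so cumulative
  edge counts accelerate and later slices are denser than earlier ones;
* a gold standard of drug-disease positives with approval years.  Signal
  is planted at the *path* level: shortly before a positive's approval
  year the generator constructs drug-drug similarity (RELATED_TO) and
  disease-disease similarity (ASSOCIATED_WITH) edges completing the
  ``CDrtCDtDO`` and ``CDtDOawDO`` metapaths, plus the pair's own TREATS
  edge dated at approval.  DWPC extraction is therefore exercised
  end-to-end; nothing is injected at the feature level.

With ``effect_size = 0`` no edges are planted and the positives are
uniform random pairs — a pure-noise control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .hetnet import Edge, HetNet, Node
from .metagraph import MetaEdge, Metagraph

PLANTABLE = ("CDrtCDtDO", "CDtDOawDO")


def default_metagraph() -> Metagraph:
    return Metagraph(
        node_types={"Compound": "CD", "Disease": "DO", "Gene": "G", "Anatomy": "A"},
        metaedges=[
            MetaEdge("Compound", "TREATS", "Disease", "t", True),
            MetaEdge("Compound", "RELATED_TO", "Compound", "rt", False),
            MetaEdge("Disease", "ASSOCIATED_WITH", "Disease", "aw", False),
            MetaEdge("Compound", "INTERACTS_WITH", "Gene", "iw", True),
            MetaEdge("Gene", "ASSOCIATED_WITH", "Disease", "aw", True),
            MetaEdge("Anatomy", "LOCATION_OF", "Compound", "lo", True),
            MetaEdge("Anatomy", "LOCATION_OF", "Disease", "lo", True),
        ],
    )


def _default_nodes() -> dict:
    return {"Compound": 160, "Disease": 100, "Gene": 60, "Anatomy": 20}


def _default_degrees() -> dict:
    # target mean degree of each metaedge's source-type nodes
    return {
        "CDtDO": 2.0,
        "CDrtCD": 3.0,
        "DOawDO": 3.0,
        "CDiwG": 2.0,
        "GawDO": 2.0,
        "AloCD": 6.0,
        "AloDO": 6.0,
    }


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    ``effect_size`` is the expected number of planted supporting paths per
    positive and per planted metapath (Poisson-distributed, or exactly
    ``max(1, round(effect_size))`` with ``deterministic_planting``).
    ``lead_years`` bounds how long before approval the supporting edges
    appear, which is what makes near-future indications easier to predict
    than far-future ones.
    """

    seed: int = 0
    n_nodes: dict = field(default_factory=_default_nodes)
    mean_degree: dict = field(default_factory=_default_degrees)
    year_start: int = 1950
    year_end: int = 2015
    growth_rate: float = 0.04
    n_positives: int = 100
    approval_start: int = 1960
    approval_end: int = 2015
    planted_metapaths: tuple = PLANTABLE
    effect_size: float = 3.0
    lead_years: int = 8
    undated_fraction: float = 0.05
    pmid_mean_extra: float = 1.0
    deterministic_planting: bool = False

    def __post_init__(self):
        if any(v <= 0 for v in self.n_nodes.values()):
            raise ConfigurationError("node counts must be positive")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not self.year_start <= self.approval_start <= self.approval_end <= self.year_end:
            raise ConfigurationError("approval years must lie inside the year range")
        for mp in self.planted_metapaths:
            if mp not in PLANTABLE:
                raise ConfigurationError(f"cannot plant metapath {mp!r}")


class SyntheticStudy(NamedTuple):
    net: HetNet
    year_map: dict
    indications: pd.DataFrame


_NODE_PREFIX = {"Compound": "C", "Disease": "D", "Gene": "G", "Anatomy": "A"}


class _PmidFactory:
    """Sequential synthetic publication ids with year bookkeeping."""

    def __init__(self, year_map: dict | None = None):
        self.year_map = dict(year_map or {})
        self._next = 1 + max(
            (int(p[2:]) for p in self.year_map if p.startswith("PM")), default=0
        )

    def publications(
        self, edge_year: int, rng: np.random.Generator, mean_extra: float,
        year_end: int, dated: bool,
    ) -> frozenset:
        n = 1 + int(rng.poisson(mean_extra))
        pmids = []
        for i in range(n):
            pmid = f"PM{self._next:07d}"
            self._next += 1
            pmids.append(pmid)
            if dated:
                year = edge_year if i == 0 else int(rng.integers(edge_year, year_end + 1))
                self.year_map[pmid] = year
        return frozenset(pmids)


def _year_weights(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    w = np.exp(cfg.growth_rate * (years - cfg.year_start))
    return years, w / w.sum()


def generate_temporal_hetnet(cfg: SynthConfig) -> tuple[HetNet, dict]:
    """Background network plus its publication-year map.

    Edge years are drawn with exponentially increasing weight toward later
    years, so the cumulative edge count grows superlinearly and the mean
    degree of every node type rises with the slice year.
    """
    rng = np.random.default_rng(cfg.seed)
    mg = default_metagraph()

    nodes: dict[str, Node] = {}
    ids_by_type: dict[str, list[str]] = {}
    for ntype in sorted(cfg.n_nodes):
        prefix = _NODE_PREFIX[ntype]
        ids = [f"{prefix}{i:04d}" for i in range(cfg.n_nodes[ntype])]
        ids_by_type[ntype] = ids
        for nid in ids:
            nodes[nid] = Node(nid, f"{ntype.lower()}-{nid}", ntype)

    years, weights = _year_weights(cfg)
    pmids = _PmidFactory()
    edges: list[Edge] = []
    seen: set[tuple[str, str, str]] = set()
    for ab in sorted(cfg.mean_degree):
        me = mg.metaedge(ab)
        srcs = ids_by_type[me.source]
        tgts = ids_by_type[me.target]
        same_undirected = not me.directed
        n_edges = int(round(cfg.mean_degree[ab] * len(srcs) / (2 if same_undirected else 1)))
        max_possible = len(srcs) * (len(tgts) - (1 if me.source == me.target else 0))
        if same_undirected:
            max_possible //= 2
        if n_edges > max_possible:
            raise ConfigurationError(
                f"mean degree for {ab} needs {n_edges} edges; only {max_possible} exist"
            )
        attempts = 0
        placed = 0
        while placed < n_edges:
            attempts += 1
            if attempts > 100 * n_edges + 1000:
                raise ConfigurationError(f"could not place {n_edges} edges of {ab}")
            s = srcs[int(rng.integers(len(srcs)))]
            t = tgts[int(rng.integers(len(tgts)))]
            if s == t:
                continue
            if same_undirected and s > t:
                s, t = t, s
            key = (s, t, ab)
            if key in seen:
                continue
            seen.add(key)
            placed += 1
            year = int(rng.choice(years, p=weights))
            dated = rng.random() >= cfg.undated_fraction
            pubs = pmids.publications(year, rng, cfg.pmid_mean_extra, cfg.year_end, dated)
            edges.append(Edge(s, t, ab, pubs, year if dated else None))

    net = HetNet(mg, nodes, edges, validate=True)
    return net, pmids.year_map


def generate_gold_standard(
    net: HetNet, cfg: SynthConfig, year_map: dict | None = None
) -> tuple[HetNet, pd.DataFrame, dict]:
    """Plant positives into a generated network.

    Returns the augmented network, the indication table (positives with
    approval years) and the extended publication-year map.  For each
    positive, supporting similarity-plus-TREATS paths are constructed with
    edge years in the ``lead_years`` window before approval, and the
    pair's own TREATS edge is dated at the approval year itself.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    compounds = list(net.node_ids("Compound"))
    diseases = list(net.node_ids("Disease"))
    if cfg.n_positives > len(compounds) * len(diseases) // 2:
        raise ConfigurationError("not enough candidate pairs for the requested positives")

    pairs: list[tuple[str, str]] = []
    taken = set()
    while len(pairs) < cfg.n_positives:
        d = compounds[int(rng.integers(len(compounds)))]
        s = diseases[int(rng.integers(len(diseases)))]
        if (d, s) in taken:
            continue
        taken.add((d, s))
        pairs.append((d, s))
    approvals = rng.integers(cfg.approval_start, cfg.approval_end + 1, size=len(pairs))

    pmids = _PmidFactory(year_map)
    new_edges: list[Edge] = []

    def planted_edge(s, t, ab, year):
        pubs = pmids.publications(year, rng, cfg.pmid_mean_extra, cfg.year_end, True)
        new_edges.append(Edge(s, t, ab, pubs, year))

    if cfg.effect_size > 0:
        for (d, s), year in zip(pairs, approvals):
            year = int(year)
            lo = max(cfg.year_start, year - cfg.lead_years)
            hi = max(lo, year - 1)

            def support_year():
                return int(rng.integers(lo, hi + 1))

            planted_edge(d, s, "CDtDO", year)
            for mp in cfg.planted_metapaths:
                if cfg.deterministic_planting:
                    n_sup = max(1, int(round(cfg.effect_size)))
                else:
                    n_sup = int(rng.poisson(cfg.effect_size))
                for _ in range(n_sup):
                    if mp == "CDrtCDtDO":
                        d2 = d
                        while d2 == d:
                            d2 = compounds[int(rng.integers(len(compounds)))]
                        planted_edge(d, d2, "CDrtCD", support_year())
                        planted_edge(d2, s, "CDtDO", support_year())
                    else:  # CDtDOawDO
                        s2 = s
                        while s2 == s:
                            s2 = diseases[int(rng.integers(len(diseases)))]
                        planted_edge(d, s2, "CDtDO", support_year())
                        planted_edge(s, s2, "DOawDO", support_year())

    augmented = net.with_edges(new_edges) if new_edges else net
    indications = pd.DataFrame(
        {
            "drug_id": [p[0] for p in pairs],
            "disease_id": [p[1] for p in pairs],
            "approval_year": [int(y) for y in approvals],
            "label": "positive",
        }
    ).sort_values(["drug_id", "disease_id"], ignore_index=True)
    return augmented, indications, pmids.year_map


def generate_dataset(cfg: SynthConfig) -> SyntheticStudy:
    """Convenience wrapper: background network, planting, gold standard."""
    net, year_map = generate_temporal_hetnet(cfg)
    net, indications, year_map = generate_gold_standard(net, cfg, year_map)
    return SyntheticStudy(net, year_map, indications)
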