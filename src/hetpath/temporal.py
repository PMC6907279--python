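"""Time-resolved network slices and past/future indication splits.

Each edge is dated by the earliest publication year among its supporting
publication ids; a network *slice* at year Y keeps the edges whose
earliest support is on or before Y, approximating the state of knowledge
at that date.  Indications (drug-treats-disease positives) are dated by
the drug's first approval year for the indication and split into a past
(training) and future (testing) set around the slice year, with the
boundary year inclusive on the training side.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError
from .hetnet import HetNet
from .metagraph import Metagraph

INDICATION_COLUMNS = ["drug_id", "disease_id", "approval_year", "label"]

#: Default slice grid: every 5 years from 1950 to the present.
DEFAULT_YEARS = tuple(range(1950, 2020, 5))


def assign_edge_years(net: HetNet, year_map: Mapping[str, int]) -> tuple[HetNet, dict]:
    """Date every edge by the minimum mapped year of its publication ids.

    Edges with no mappable publication id become undated (year ``None``)
    and are counted in the report; undated edges are excluded from every
    time slice but retained in the full network.
    """
    dated = []
    n_undated = 0
    for e in net.edges:
        years = [year_map[p] for p in e.pmids if p in year_map]
        year = min(years) if years else None
        if year is None:
            n_undated += 1
        dated.append(replace(e, year=year))
    out = HetNet(net.metagraph, net.nodes, dated, validate=False)
    return out, {"undated_edges": n_undated, "dated_edges": net.n_edges - n_undated}


def slice_network(net: HetNet, year: int) -> HetNet:
    """Edges dated on or before ``year``; prunes empty nodes and metaedges."""
    sliced = net.filter_edges(lambda e: e.year is not None and e.year <= year)
    sliced = sliced.drop_isolated_nodes()
    present = {e.metaedge for e in sliced.edges}
    keep = [
        me
        for me in sliced.metagraph.metaedges
        if sliced.metagraph.abbrev(me) in present
    ]
    if len(keep) != len(sliced.metagraph.metaedges):
        sliced = sliced.with_metagraph(
            Metagraph(sliced.metagraph.node_types, keep)
        )
    return sliced


def slice_series(net: HetNet, years: Sequence[int] = DEFAULT_YEARS) -> dict[int, HetNet]:
    """Slices at each requested year (nested by construction)."""
    return {y: slice_network(net, y) for y in years}


def validate_indications(ind: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INDICATION_COLUMNS if c not in ind.columns]
    if missing:
        raise SchemaError(f"indication table missing columns {missing}")
    dup = ind.duplicated(subset=["drug_id", "disease_id"])
    if dup.any():
        raise SchemaError("duplicate (drug, disease) rows in indication table")
    pos = ind["label"] == "positive"
    if ind.loc[pos, "approval_year"].isna().any():
        raise SchemaError("positive indications must carry an approval year")
    return ind


def split_indications(
    ind: pd.DataFrame, net_slice: HetNet, year: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition positives into (train, test, dropped) around ``year``.

    Positives approved in or before the slice year train; later ones test.
    A positive whose drug or disease is absent from the slice (no longer
    connected to any concept) is dropped from both.
    """
    ind = validate_indications(ind)
    pos = ind[ind["label"] == "positive"].copy()
    connected = pos["drug_id"].isin(net_slice.nodes) & pos["disease_id"].isin(
        net_slice.nodes
    )
    dropped = pos[~connected]
    pos = pos[connected]
    train = pos[pos["approval_year"] <= year]
    test = pos[pos["approval_year"] > year]
    return (
        train.reset_index(drop=True),
        test.reset_index(drop=True),
        dropped.reset_index(drop=True),
    )


def read_indications(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "disease_id": str})
    df["approval_year"] = pd.to_numeric(df["approval_year"], errors="coerce")
    return validate_indications(df)


def write_indications(ind: pd.DataFrame, path) -> None:
    out = ind[INDICATION_COLUMNS].sort_values(["drug_id", "disease_id"])
    out.to_csv(path, sep="\t", index=False)
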