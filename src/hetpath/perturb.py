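"""Edge-dropout and edge-replacement ablations.

Both experiments quantify how much one edge type contributes to the
trained model.  *Dropout* removes a random fraction of one metaedge's
edges (several replicate seeds per rate) and retrains; *replacement*
swaps one metaedge's edges for their state in another year's network
slice — substituting a later, denser slice simulates acquiring future
knowledge of that type.  The test set and negative samples are frozen
across every condition of a suite, so metric deltas reflect the
perturbation alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IdentifierError
from .hetnet import HetNet
from .learn import ModelConfig, make_year_split, run_year


@dataclass
class PerturbationPlan:
    """One ablation experiment on a base-year network."""

    base_year: int
    metaedge: str
    mode: str  # "dropout" | "replace"
    rates: tuple[float, ...] = (25, 50, 75, 100)
    replicates: int = 5
    donor_years: tuple[int, ...] = ()

    def __post_init__(self):
        if self.mode not in ("dropout", "replace"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "dropout" and any(not 0 < r <= 100 for r in self.rates):
            raise ConfigurationError("dropout rates must lie in (0, 100]")
        if self.replicates < 1:
            raise ConfigurationError("replicate count must be >= 1")
        if self.mode == "replace" and not self.donor_years:
            raise ConfigurationError("replace mode needs donor_years")


def dropout_edges(net: HetNet, metaedge_abbrev: str, rate: float, seed: int) -> HetNet:
    """Remove ``floor(rate/100 * n)`` uniformly chosen edges of one metaedge."""
    if not 0 < rate <= 100:
        raise ConfigurationError("rate must be in (0, 100]")
    edges = net.edges_of(metaedge_abbrev)  # raises IdentifierError if unknown
    n_drop = int(rate / 100 * len(edges))
    rng = np.random.default_rng(seed)
    drop_idx = set(rng.choice(len(edges), size=n_drop, replace=False).tolist())
    dropped = {edges[i].key for i in drop_idx}
    return net.filter_edges(lambda e: e.key not in dropped)


def replace_edge_type(
    base: HetNet, donor: HetNet, metaedge_abbrev: str
) -> tuple[HetNet, dict]:
    """Swap one metaedge's edges for the donor slice's version.

    The base node set is held constant: donor edges with an endpoint
    absent from the base network are not inserted (counted in the report).
    """
    in_base = metaedge_abbrev in base.metagraph.metaedge_abbrevs
    in_donor = metaedge_abbrev in donor.metagraph.metaedge_abbrevs
    if not in_base and not in_donor:
        raise IdentifierError(f"metaedge {metaedge_abbrev!r} absent from both networks")
    stripped = base.filter_edges(lambda e: e.metaedge != metaedge_abbrev)
    insert = []
    n_skipped = 0
    donor_edges = donor.edges_of(metaedge_abbrev) if in_donor else ()
    for e in donor_edges:
        if e.source in base.nodes and e.target in base.nodes:
            insert.append(e)
        else:
            n_skipped += 1
    return stripped.with_edges(insert), {
        "inserted": len(insert),
        "skipped_missing_endpoint": n_skipped,
    }


def run_perturbation_suite(
    slices: Mapping[int, HetNet],
    indications: pd.DataFrame,
    cfg: ModelConfig,
    plans: list[PerturbationPlan],
) -> tuple[pd.DataFrame, float]:
    """Retrain under every planned condition against a frozen baseline.

    All plans must share one base year.  Returns the per-condition result
    table (with ΔAUROC/ΔAUPRC against the unperturbed baseline) and the
    baseline AUROC.  A condition that fails to train is recorded as a
    failed row and the suite continues.
    """
    base_years = {p.base_year for p in plans}
    if len(base_years) != 1:
        raise ConfigurationError("all plans in a suite must share the base year")
    base_year = base_years.pop()
    base_net = slices[base_year]

    seed = int(np.random.default_rng(cfg.seed).integers(2**31))
    split = make_year_split(base_net, indications, base_year, cfg, seed)
    if split is None:
        raise ConfigurationError(f"base year {base_year} has too few training positives")
    baseline = run_year(base_net, split, cfg)
    if baseline.auroc is None:
        raise ConfigurationError(f"base year {base_year} has no future positives")

    rows = []

    def run_condition(net, plan, condition, replicate):
        try:
            res = run_year(net, split, cfg)
            rows.append(
                {
                    "metaedge": plan.metaedge,
                    "mode": plan.mode,
                    "condition": condition,
                    "replicate": replicate,
                    "auroc": res.auroc,
                    "auprc": res.auprc,
                    "delta_auroc": res.auroc - baseline.auroc,
                    "delta_auprc": res.auprc - baseline.auprc,
                    "failed": False,
                }
            )
        except Exception:  # a failed condition must not kill the suite
            rows.append(
                {
                    "metaedge": plan.metaedge,
                    "mode": plan.mode,
                    "condition": condition,
                    "replicate": replicate,
                    "auroc": np.nan,
                    "auprc": np.nan,
                    "delta_auroc": np.nan,
                    "delta_auprc": np.nan,
                    "failed": True,
                }
            )

    for plan in plans:
        if plan.mode == "dropout":
            for rate in plan.rates:
                for rep in range(plan.replicates):
                    net = dropout_edges(
                        base_net, plan.metaedge, rate, seed=seed + 7919 * rep
                    )
                    run_condition(net, plan, float(rate), rep)
        else:
            for donor_year in plan.donor_years:
                net, _rep = replace_edge_type(
                    base_net, slices[donor_year], plan.metaedge
                )
                run_condition(net, plan, int(donor_year), 0)

    return pd.DataFrame(rows), baseline.auroc


def ci_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ΔAUROC with a 95% CI (mean ± 1.96·sd/√n) per condition."""
    ok = results[~results["failed"]]
    grouped = ok.groupby(["metaedge", "mode", "condition"])["delta_auroc"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    half = 1.96 * out["std"] / np.sqrt(out["count"])
    out["ci_low"] = out["mean"] - half
    out["ci_high"] = out["mean"] + half
    return out
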