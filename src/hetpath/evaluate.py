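"""Metrics and cross-model temporal aggregation.

Besides plain AUROC/AUPRC and rank statistics, this module combines the
per-year time-split models into a single relative-approval-year curve:
each model's probabilities are z-scored (so models are comparable), every
gold positive is binned by ``approval year − network year``, and per-bin
AUROC/AUPRC is computed against a pooled 10:1 negative sample drawn once
across all models.  A centered 5-year rolling mean smooths the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import MetricUndefinedError


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic with midrank ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricUndefinedError("AUROC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Average precision (step-wise integral of the PR curve)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricUndefinedError("AUPRC requires both classes")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# -------------------------------------------------------------------- ranking
@dataclass
class RankResult:
    by_source: pd.DataFrame  # query, slate_size, rank (one row per positive)
    by_target: pd.DataFrame
    median_target_rank: float | None  # rank of true diseases given a drug
    median_source_rank: float | None  # rank of true drugs given a disease
    skipped: list


def rank_holdouts(predictions: pd.DataFrame) -> RankResult:
    """Per-query ranks of true positives within each candidate slate.

    ``predictions`` needs columns source, target, probability, label and
    must cover the full candidate slate per query entity.  Rank is
    1 + the number of candidates scored strictly higher; ties receive the
    average rank.  A query with positives but no other candidates is
    skipped and reported.
    """
    skipped: list = []

    def one_direction(query_col: str) -> pd.DataFrame:
        rows = []
        for query, grp in predictions.groupby(query_col, sort=True):
            if grp["label"].sum() == 0:
                continue
            if len(grp) < 2:
                skipped.append(query)
                continue
            ranks = rankdata(-grp["probability"].to_numpy(), method="average")
            for r, lab in zip(ranks, grp["label"]):
                if lab == 1:
                    rows.append(
                        {"query": query, "slate_size": len(grp), "rank": float(r)}
                    )
        return pd.DataFrame(rows, columns=["query", "slate_size", "rank"])

    by_source = one_direction("source")
    by_target = one_direction("target")
    return RankResult(
        by_source,
        by_target,
        float(by_source["rank"].median()) if len(by_source) else None,
        float(by_target["rank"].median()) if len(by_target) else None,
        skipped,
    )


# ------------------------------------------------------------- z-score pooling
def standardize_probabilities(
    predictions: pd.DataFrame,
    model_col: str = "network_year",
    score_col: str = "probability",
) -> tuple[pd.DataFrame, list]:
    """Per-model z-scores over all scored pairs (population sd).

    Models with zero score variance are excluded and reported; the
    transform is monotone within a model, so orderings are preserved.
    """
    out = []
    excluded = []
    for model, grp in predictions.groupby(model_col, sort=True):
        if len(grp) < 2:
            excluded.append(model)
            continue
        x = grp[score_col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            excluded.append(model)
            continue
        grp = grp.copy()
        grp["z"] = (x - x.mean()) / sd
        out.append(grp)
    if not out:
        raise MetricUndefinedError("no model with score variance to standardize")
    return pd.concat(out, ignore_index=True), excluded


def relative_year_curve(
    predictions: pd.DataFrame,
    ratio: float = 10,
    seed: int = 0,
    offset_range: tuple[int, int] = (-20, 20),
    window: int = 5,
) -> pd.DataFrame:
    """Per-offset AUROC/AUPRC of positives against pooled negatives.

    ``predictions`` holds standardized scores (column ``z``) from all
    models, with ``label``, ``network_year`` and, for positives,
    ``approval_year``.  The offset of a positive is
    ``approval_year − network_year``; bins without positives are absent
    from the result, not zero.  Negatives are drawn once globally with
    ``seed`` at ``ratio`` times the number of binned positives (the whole
    pool if smaller).  The smoothed series is a centered ``window``-year
    rolling mean, shrinking at the edges.
    """
    lo, hi = offset_range
    pos = predictions[(predictions["label"] == 1)].copy()
    pos = pos[pos["approval_year"].notna()]
    pos["offset"] = (pos["approval_year"] - pos["network_year"]).round().astype(int)
    pos = pos[(pos["offset"] >= lo) & (pos["offset"] <= hi)]
    neg_pool = predictions[predictions["label"] == 0]
    if pos.empty or neg_pool.empty:
        raise MetricUndefinedError("need positives in range and a negative pool")

    rng = np.random.default_rng(seed)
    n_neg = min(int(ratio * len(pos)), len(neg_pool))
    neg_z = neg_pool["z"].to_numpy(dtype=float)
    neg_sample = neg_z[np.sort(rng.choice(len(neg_z), size=n_neg, replace=False))]

    rows = []
    for off, grp in pos.groupby("offset", sort=True):
        scores = np.concatenate([grp["z"].to_numpy(dtype=float), neg_sample])
        labels = np.concatenate([np.ones(len(grp)), np.zeros(n_neg)])
        rows.append(
            {
                "offset": int(off),
                "auroc": auroc(scores, labels),
                "auprc": auprc(scores, labels),
                "n_pos": len(grp),
            }
        )
    curve = pd.DataFrame(rows).set_index("offset")
    full = curve.reindex(range(lo, hi + 1))
    for col in ("auroc", "auprc"):
        full[f"{col}_smooth"] = (
            full[col].rolling(window, center=True, min_periods=1).mean()
        )
    curve = full.loc[curve.index].reset_index()
    curve["n_pos"] = curve["n_pos"].astype(int)
    return curve


def offset_band_auroc(
    predictions: pd.DataFrame,
    band: tuple[int, int],
    ratio: float = 10,
    seed: int = 0,
) -> float:
    """AUROC of all positives whose offset falls in ``band`` (inclusive)
    against a pooled 10:1 negative sample — a coarse view of the curve."""
    pos = predictions[(predictions["label"] == 1)].copy()
    pos = pos[pos["approval_year"].notna()]
    off = (pos["approval_year"] - pos["network_year"]).round().astype(int)
    pos = pos[(off >= band[0]) & (off <= band[1])]
    neg_pool = predictions[predictions["label"] == 0]
    if pos.empty or neg_pool.empty:
        raise MetricUndefinedError(f"no positives with offset in {band}")
    rng = np.random.default_rng(seed)
    n_neg = min(int(ratio * len(pos)), len(neg_pool))
    neg_z = neg_pool["z"].to_numpy(dtype=float)
    neg_sample = neg_z[np.sort(rng.choice(len(neg_z), size=n_neg, replace=False))]
    scores = np.concatenate([pos["z"].to_numpy(dtype=float), neg_sample])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(n_neg)])
    return auroc(scores, labels)
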