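"""ElasticNet logistic models over DWPC features.

The learning task is binary: gold-standard drug-disease indications are
the positives, negatives are sampled uniformly from the non-positive
drug-disease pairs at a 10:1 ratio.  Features are transformed before
fitting (per-column mean scaling, inverse hyperbolic sine, then
z-scoring), with transformation parameters frozen on the training rows
and reused verbatim at prediction time.

Two evaluation regimes are provided: k-fold cross-validation partitioned
by indication (with the holdout pairs' TREATS edges removed from the
network *before* feature extraction, so the model cannot read the answer
off the direct edge), and time-split training where models learn from a
past network slice and past approvals and are tested on indications
approved later.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .dwpc import FeatureConfig, extract_features
from .errors import ConfigurationError, SamplingError, SchemaError
from .hetnet import HetNet
from .temporal import split_indications

Pair = tuple[str, str]


@dataclass
class ModelConfig:
    """Hyperparameters and run settings for the ElasticNet logistic model.

    ``alpha`` is the ElasticNet mixing parameter (1 = lasso, 0 = ridge)
    and ``c_grid`` the inverse-regularization-strength grid; with more
    than one value the strength is chosen by internal cross-validated
    log-loss, with a single value it is frozen (the default: tuned once,
    then held constant across every run and perturbation, so that metric
    deltas between conditions never reflect a flipped selector).
    ``feature.w`` is the DWPC damping exponent shared with feature
    extraction.  ``target_metaedge`` names the TREATS-like metaedge whose
    held-out instances define the prediction task.
    """

    feature: FeatureConfig
    target_metaedge: str
    alpha: float = 0.7
    c_grid: tuple[float, ...] = (0.3,)
    negative_ratio: int = 10
    n_folds: int = 5
    n_repeats: int = 10
    inner_cv: int = 3
    transform: str = "asinh"
    max_iter: int = 5000
    tol: float = 1e-4
    min_train_positives: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ConfigurationError("alpha must be in [0, 1]")
        if not self.c_grid:
            raise ConfigurationError("c_grid must be nonempty")
        if self.negative_ratio <= 0:
            raise ConfigurationError("negative_ratio must be > 0")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.transform not in ("asinh", "zscore"):
            raise ConfigurationError(f"unknown transform {self.transform!r}")


# ----------------------------------------------------------------- transform
def transform_features(
    ft: pd.DataFrame,
    params: dict | None = None,
    kind: str = "asinh",
) -> tuple[pd.DataFrame, dict]:
    """Scale and standardize a feature table.

    With ``kind="asinh"`` each DWPC column x is mapped to
    ``asinh(x / mean(x))`` then z-scored; degree columns are asinh-mapped
    then z-scored.  ``kind="zscore"`` z-scores raw values.  The z-score
    uses the sample standard deviation (ddof=1).  Zero-mean or
    zero-variance columns map to all-zeros and the degenerate case is
    recorded in the returned parameters.

    Pass the returned ``params`` back in to apply the frozen training
    transform to new rows (columns must match exactly).
    """
    if params is not None:
        if list(ft.columns) != list(params["columns"]):
            raise SchemaError("feature columns do not match fitted transform")
        kind = params["kind"]

    fitted = params is None
    cols: dict[str, tuple] = {} if fitted else params["cols"]
    out = {}
    for col in ft.columns:
        x = ft[col].to_numpy(dtype=float)
        if fitted:
            scale_mean = None
            if kind == "asinh":
                if col.startswith("dwpc_"):
                    m = float(x.mean())
                    scale_mean = m if m > 0 else 0.0
                else:
                    scale_mean = -1.0  # marker: asinh without mean scaling
            xt = _pre_transform(x, scale_mean)
            mu = float(xt.mean())
            sd = float(xt.std(ddof=1)) if len(xt) > 1 else 0.0
            cols[col] = (scale_mean, mu, sd)
        else:
            scale_mean, mu, sd = cols[col]
            xt = _pre_transform(x, scale_mean)
        out[col] = np.zeros(len(x)) if sd == 0 else (xt - mu) / sd
    new_params = {"kind": kind, "columns": tuple(ft.columns), "cols": cols}
    return pd.DataFrame(out, index=ft.index), new_params


def _pre_transform(x: np.ndarray, scale_mean: float | None) -> np.ndarray:
    if scale_mean is None:  # plain z-score regime
        return x
    if scale_mean == 0.0:  # degenerate all-zero training column
        return np.zeros_like(x)
    if scale_mean == -1.0:  # degree column: asinh only
        return np.arcsinh(x)
    return np.arcsinh(x / scale_mean)


# ----------------------------------------------------------------- negatives
def candidate_universe(
    net: HetNet, source_type: str, target_type: str, exclude: Iterable[Pair]
) -> list[Pair]:
    """All (source, target) node pairs of the net minus the excluded set."""
    excluded = set(exclude)
    return [
        (s, t)
        for s in net.node_ids(source_type)
        for t in net.node_ids(target_type)
        if (s, t) not in excluded
    ]


def sample_negatives(
    positives: Sequence[Pair],
    universe: Sequence[Pair],
    ratio: float = 10,
    seed: int = 0,
) -> list[Pair]:
    """Uniform sample (without replacement) of ``ratio * len(positives)`` pairs.

    The universe must already exclude every gold positive, past and future.
    """
    pos = set(positives)
    overlap = pos.intersection(universe)
    if overlap:
        raise SamplingError(f"universe contains positives, e.g. {sorted(overlap)[:3]}")
    n = int(ratio * len(positives))
    if n > len(universe):
        raise SamplingError(
            f"cannot draw {n} negatives from a universe of {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    ordered = sorted(universe)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(idx)]


# ------------------------------------------------------------------- fitting
def _fit_enet(X: np.ndarray, y: np.ndarray, cfg: ModelConfig, seed: int):
    seed = int(seed) % (2**31)
    if len(cfg.c_grid) == 1:
        model = LogisticRegression(
            solver="saga",
            C=cfg.c_grid[0],
            l1_ratio=cfg.alpha,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            random_state=seed,
        )
    else:
        model = LogisticRegressionCV(
            Cs=list(cfg.c_grid),
            cv=cfg.inner_cv,
            solver="saga",
            l1_ratios=[cfg.alpha],
            scoring="neg_log_loss",
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            random_state=seed,
            refit=True,
            use_legacy_attributes=False,
        )
    model.fit(X, y)
    return model


def fit_predict(
    net: HetNet,
    train_pos: Sequence[Pair],
    train_neg: Sequence[Pair],
    score_pairs: Sequence[Pair],
    cfg: ModelConfig,
    seed: int,
) -> tuple[np.ndarray, pd.Series]:
    """Extract, transform, fit, and score; returns (probabilities, coefficients).

    ``score_pairs`` may overlap the training pairs; features are extracted
    once over the union and the transform is frozen on the training rows.
    """
    train_pairs = list(train_pos) + list(train_neg)
    all_pairs = list(dict.fromkeys(train_pairs + list(score_pairs)))
    ft = extract_features(net, all_pairs, cfg.feature)
    train_ft = ft.loc[train_pairs]
    train_X, params = transform_features(train_ft, kind=cfg.transform)
    y = np.array([1] * len(train_pos) + [0] * len(train_neg))
    if y.min() == y.max():
        raise ConfigurationError("training data contains a single class")
    model = _fit_enet(train_X.to_numpy(), y, cfg, seed)
    score_X, _ = transform_features(ft.loc[list(score_pairs)], params=params)
    probs = model.predict_proba(score_X.to_numpy())[:, 1]
    coefs = pd.Series(np.ravel(model.coef_), index=ft.columns, name="coef")
    return probs, coefs


# ---------------------------------------------------------- cross-validation
@dataclass
class CVResult:
    metrics: pd.DataFrame  # repeat, fold, auroc, auprc, n_test_pos, n_test_neg
    predictions: pd.DataFrame  # source, target, probability, label, repeat, fold
    coefs: pd.DataFrame  # long form: repeat, fold, feature, coef

    @property
    def mean_auroc(self) -> float:
        return float(self.metrics["auroc"].mean())

    @property
    def mean_auprc(self) -> float:
        return float(self.metrics["auprc"].mean())

    def coefficient_ranks(self) -> pd.Series:
        """Features ranked by mean |coefficient| across folds (1 = largest)."""
        mean_abs = self.coefs.groupby("feature")["coef"].apply(
            lambda s: s.abs().mean()
        )
        return mean_abs.rank(ascending=False, method="min").sort_values()


def _partition(items: list, k: int, rng: np.random.Generator) -> list[list]:
    order = rng.permutation(len(items))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(items[idx])
    return folds


def cv_run(net: HetNet, indications: pd.DataFrame, cfg: ModelConfig) -> CVResult:
    """Repeated k-fold cross-validation partitioned by indication.

    Per fold, the holdout positives' TREATS edges are removed from the
    network and features are re-extracted before fitting, so holdout
    indications cannot be read off their own edge.
    """
    from .evaluate import auprc, auroc  # local import to avoid a cycle

    pos_df = indications[indications["label"] == "positive"]
    positives = [
        (r.drug_id, r.disease_id)
        for r in pos_df.itertuples(index=False)
        if r.drug_id in net.nodes and r.disease_id in net.nodes
    ]
    if len(positives) < cfg.n_folds:
        raise ConfigurationError(
            f"{len(positives)} positives cannot fill {cfg.n_folds} folds"
        )
    all_pos_pairs = set(
        zip(pos_df["drug_id"], pos_df["disease_id"])
    )
    universe = candidate_universe(
        net, cfg.feature.source_type, cfg.feature.target_type, all_pos_pairs
    )

    root = np.random.default_rng(cfg.seed)
    metric_rows, pred_rows, coef_rows = [], [], []
    for repeat in range(cfg.n_repeats):
        rep_seed = int(root.integers(2**31))
        rng = np.random.default_rng(rep_seed)
        negatives = sample_negatives(
            positives, universe, cfg.negative_ratio, seed=rep_seed
        )
        pos_folds = _partition(positives, cfg.n_folds, rng)
        neg_folds = _partition(negatives, cfg.n_folds, rng)
        for fold in range(cfg.n_folds):
            hold_pos, hold_neg = pos_folds[fold], neg_folds[fold]
            if not hold_pos:
                raise ConfigurationError(f"fold {fold} has zero positives")
            train_pos = [p for f in range(cfg.n_folds) if f != fold for p in pos_folds[f]]
            train_neg = [p for f in range(cfg.n_folds) if f != fold for p in neg_folds[f]]
            net_fold = net.without_pair_edges(cfg.target_metaedge, hold_pos)
            score_pairs = hold_pos + hold_neg
            probs, coefs = fit_predict(
                net_fold, train_pos, train_neg, score_pairs, cfg, seed=rep_seed + fold
            )
            labels = np.array([1] * len(hold_pos) + [0] * len(hold_neg))
            metric_rows.append(
                {
                    "repeat": repeat,
                    "fold": fold,
                    "auroc": auroc(probs, labels),
                    "auprc": auprc(probs, labels),
                    "n_test_pos": len(hold_pos),
                    "n_test_neg": len(hold_neg),
                }
            )
            for (s, t), p, lab in zip(score_pairs, probs, labels):
                pred_rows.append(
                    {
                        "source": s,
                        "target": t,
                        "probability": p,
                        "label": lab,
                        "repeat": repeat,
                        "fold": fold,
                    }
                )
            for feat, c in coefs.items():
                coef_rows.append(
                    {"repeat": repeat, "fold": fold, "feature": feat, "coef": c}
                )
    return CVResult(
        pd.DataFrame(metric_rows),
        pd.DataFrame(pred_rows),
        pd.DataFrame(coef_rows),
    )


# ----------------------------------------------------------------- time-split
@dataclass
class YearSplit:
    """Frozen inputs for one network-year model (reused across perturbations)."""

    year: int
    train_pos: list[Pair]
    test_pos: list[Pair]
    neg_train: list[Pair]
    neg_test: list[Pair]
    approval: dict[Pair, float]
    n_dropped: int
    seed: int


@dataclass
class YearResult:
    year: int
    auroc: float | None
    auprc: float | None
    n_train_pos: int
    n_test_pos: int
    n_dropped: int
    coefs: pd.Series
    predictions: pd.DataFrame  # source, target, probability, label, split, network_year


def make_year_split(
    net_slice: HetNet,
    indications: pd.DataFrame,
    year: int,
    cfg: ModelConfig,
    seed: int,
) -> YearSplit | None:
    """Past/future positives plus an 80:20 split of 10:1 sampled negatives.

    Returns ``None`` when the slice has too few past positives to train.
    Negatives are drawn from the slice's candidate pairs excluding every
    gold positive, at ``negative_ratio`` times the total (past and future)
    positive count.
    """
    train_df, test_df, dropped = split_indications(indications, net_slice, year)
    train_pos = list(zip(train_df["drug_id"], train_df["disease_id"]))
    test_pos = list(zip(test_df["drug_id"], test_df["disease_id"]))
    if len(train_pos) < max(cfg.min_train_positives, 1):
        return None
    pos_df = indications[indications["label"] == "positive"]
    all_pos_pairs = set(zip(pos_df["drug_id"], pos_df["disease_id"]))
    universe = candidate_universe(
        net_slice, cfg.feature.source_type, cfg.feature.target_type, all_pos_pairs
    )
    negatives = sample_negatives(
        train_pos + test_pos, universe, cfg.negative_ratio, seed=seed
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(negatives))
    n_test = len(negatives) // 5
    neg_test = [negatives[i] for i in sorted(order[:n_test])]
    neg_train = [negatives[i] for i in sorted(order[n_test:])]
    approval = {
        (r.drug_id, r.disease_id): float(r.approval_year)
        for r in pd.concat([train_df, test_df]).itertuples(index=False)
    }
    return YearSplit(
        year, train_pos, test_pos, neg_train, neg_test, approval, len(dropped), seed
    )


def run_year(net_slice: HetNet, split: YearSplit, cfg: ModelConfig) -> YearResult:
    """Train on past positives + 80% negatives; score everything.

    Test metrics are computed on future positives and the held-out 20%
    negatives; with zero future positives the metrics are reported as
    absent (``None``), never as zero.
    """
    from .evaluate import auprc, auroc

    score_pairs = split.train_pos + split.neg_train + split.test_pos + split.neg_test
    probs, coefs = fit_predict(
        net_slice, split.train_pos, split.neg_train, score_pairs, cfg, seed=split.seed
    )
    labels = (
        [1] * len(split.train_pos)
        + [0] * len(split.neg_train)
        + [1] * len(split.test_pos)
        + [0] * len(split.neg_test)
    )
    splits = (
        ["train"] * (len(split.train_pos) + len(split.neg_train))
        + ["test"] * (len(split.test_pos) + len(split.neg_test))
    )
    preds = pd.DataFrame(
        {
            "source": [p[0] for p in score_pairs],
            "target": [p[1] for p in score_pairs],
            "probability": probs,
            "label": labels,
            "split": splits,
            "network_year": split.year,
        }
    )
    preds["approval_year"] = [
        split.approval.get(p, np.nan) for p in score_pairs
    ]
    test_mask = preds["split"] == "test"
    test = preds[test_mask]
    if len(split.test_pos) == 0:
        roc = prc = None
    else:
        roc = auroc(test["probability"], test["label"])
        prc = auprc(test["probability"], test["label"])
    return YearResult(
        split.year,
        roc,
        prc,
        len(split.train_pos),
        len(split.test_pos),
        split.n_dropped,
        coefs,
        preds,
    )


def timesplit_run(
    slices: Mapping[int, HetNet],
    indications: pd.DataFrame,
    cfg: ModelConfig,
) -> dict[int, YearResult]:
    """One past-trained, future-tested model per network year."""
    root = np.random.default_rng(cfg.seed)
    results: dict[int, YearResult] = {}
    for year in sorted(slices):
        seed = int(root.integers(2**31))
        split = make_year_split(slices[year], indications, year, cfg, seed)
        if split is None:
            continue
        results[year] = run_year(slices[year], split, cfg)
    return results
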