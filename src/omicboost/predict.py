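"""Cross-prediction with gradient-boosted tree ensembles.

Any omics block (or concatenation of blocks) can be used to predict a
continuous trait or a binary class.  Tree boosting handles p >> n,
nonlinearity and missing predictor values natively, so no imputation step
exists.  Generalization is assessed on held-out samples only, with
replicate-aware splitting so biological replicates never straddle a
train/test boundary; the headline metric is the mean test R² (or accuracy)
over several such splits.  Models are interrogated through tree-path-
dependent Shapley attributions (TreeSHAP): per-sample, per-feature
contributions that together with a base value reconstruct each prediction
exactly, from which global importances, feature directions, and
Boruta-style shadow-feature selections are derived.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .io import (OmicsBlock, OutcomeVector, SampleMetadata, ValidationError,
                 logger)

DIRECTION_DEAD_ZONE = 0.1  # |corr| below which a feature direction is 0


# ---------------------------------------------------------------------------
# Specs and configs
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """How to partition samples into train/test sets.

    ``random`` draws ``train_fraction`` of the samples; ``by_replicate``
    holds out whole replicate groups (never separating samples that share a
    ``group_factor`` level); ``leave_group_out`` makes one split per group
    level.  ``n_repeats`` independent splits are produced for the first two
    modes (default 3), all deterministic given ``seed``.
    """

    mode: str = "by_replicate"
    train_fraction: float = 0.75
    group_factor: str = "replicate"
    seed: int = 0
    n_repeats: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("random", "by_replicate", "leave_group_out"):
            raise ValidationError(f"unknown split mode {self.mode!r}")
        if not (0 < self.train_fraction < 1):
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass
class BoostConfig:
    """XGBoost hyperparameters.

    ``n_rounds`` and ``max_depth`` are the two tuned knobs; the remaining
    parameters are preset to conventional values and overridable.
    ``monotone`` is an optional per-feature vector in {-1, 0, +1} enforcing
    a non-increasing / unconstrained / non-decreasing response.
    """

    n_rounds: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    gamma: float = 0.0
    subsample: float = 0.8
    colsample: float = 0.8
    min_child_weight: float = 1.0
    objective: str = "squared-error"
    monotone: tuple[int, ...] | None = None
    seed: int = 0
    nthread: int = 1  # single-thread default: bit-reproducible metrics

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.max_depth < 1:
            raise ValidationError("n_rounds and max_depth must be >= 1")
        if self.objective not in ("squared-error", "logistic"):
            raise ValidationError(f"unknown objective {self.objective!r}")
        if self.monotone is not None:
            self.monotone = tuple(int(m) for m in self.monotone)
            if any(m not in (-1, 0, 1) for m in self.monotone):
                raise ValidationError("monotone entries must be -1, 0 or +1")

    def xgb_params(self, n_features: int) -> dict:
        if self.monotone is not None and len(self.monotone) != n_features:
            raise ValidationError(
                f"monotone vector length {len(self.monotone)} != feature "
                f"count {n_features}")
        params = {
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "gamma": self.gamma,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample,
            "min_child_weight": self.min_child_weight,
            "objective": ("reg:squarederror" if self.objective == "squared-error"
                          else "binary:logistic"),
            "seed": int(self.seed),
            "nthread": int(self.nthread),
            "tree_method": "hist",
        }
        if self.monotone is not None and any(self.monotone):
            params["monotone_constraints"] = \
                "(" + ",".join(str(m) for m in self.monotone) + ")"
        return params


@dataclass
class BoostModel:
    """A fitted cross-prediction model.

    ``booster`` is trained on all samples and backs interpretation
    (SHAP, interactions); ``split_boosters`` hold one model per train/test
    split, whose held-out metrics populate ``metrics`` (one row per split)
    and ``mean_metrics``.
    """

    booster: xgb.Booster
    split_boosters: list[xgb.Booster]
    config: BoostConfig
    split: SplitSpec
    feature_ids: list[str]
    metrics: pd.DataFrame
    mean_metrics: dict[str, float]
    task: str = "regression"
    constraint_table: "object | None" = None  # ConstraintTable when constrained


@dataclass
class ShapResult:
    """Per-sample Shapley attributions for one model.

    ``base_value`` + row-sum of ``attributions`` reproduces the model's
    (margin) prediction for every sample.  ``importance`` is the mean
    absolute attribution per feature; ``direction`` the sign of the
    Pearson correlation between a feature's values and its attributions,
    zeroed inside a +/-0.1 dead zone.
    """

    attributions: pd.DataFrame  # samples x features
    base_value: float
    importance: pd.Series
    direction: pd.Series


# ---------------------------------------------------------------------------
# Block assembly and splitting
# ---------------------------------------------------------------------------

def concat_blocks(blocks: Sequence[OmicsBlock],
                  name: str = "combined") -> OmicsBlock:
    """Feature-wise concatenation of sample-aligned blocks.

    Feature ids get their block name as prefix (``"ftir:2002"``) so
    provenance survives the merge.
    """
    if not blocks:
        raise ValidationError("concat_blocks needs at least one block")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValidationError(
                f"blocks not sample-aligned ('{blocks[0].name}' vs '{b.name}')")
    feature_ids = [f"{b.name}:{f}" for b in blocks for f in b.feature_ids]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValidationError("feature-id collision after block prefixing")
    values = np.vstack([b.values for b in blocks])
    return OmicsBlock(name, feature_ids, list(ref), values)


def make_splits(metadata: SampleMetadata | None,
                spec: SplitSpec,
                sample_ids: Sequence[str] | None = None
                ) -> list[tuple[list[str], list[str]]]:
    """Produce deterministic train/test id partitions per the split spec."""
    if sample_ids is None:
        if metadata is None:
            raise ValidationError("make_splits needs metadata or sample_ids")
        sample_ids = metadata.sample_ids
    ids = [str(s) for s in sample_ids]
    rng = np.random.default_rng(spec.seed)
    splits: list[tuple[list[str], list[str]]] = []

    if spec.mode == "random":
        n_train = round(spec.train_fraction * len(ids))
        if not (0 < n_train < len(ids)):
            raise ValidationError("train_fraction leaves an empty train or test set")
        for _ in range(spec.n_repeats):
            perm = rng.permutation(len(ids))
            train = sorted(ids[i] for i in perm[:n_train])
            test = sorted(ids[i] for i in perm[n_train:])
            splits.append((train, test))
        return splits

    if metadata is None:
        raise ValidationError(f"mode {spec.mode!r} requires metadata")
    levels = metadata.subset(ids).factor(spec.group_factor)
    groups = {lv: [s for s in ids if levels[s] == lv]
              for lv in pd.unique(levels)}
    if len(groups) < 2:
        raise ValidationError(
            f"grouped splitting needs >= 2 levels of {spec.group_factor!r}, "
            f"got {len(groups)}")

    if spec.mode == "leave_group_out":
        for lv in groups:
            test = groups[lv]
            train = [s for s in ids if s not in set(test)]
            splits.append((train, test))
        return splits

    # by_replicate: hold out whole groups amounting to ~1 - train_fraction
    level_list = list(groups)
    n_test_groups = max(1, round((1 - spec.train_fraction) * len(level_list)))
    n_test_groups = min(n_test_groups, len(level_list) - 1)
    for _ in range(spec.n_repeats):
        perm = rng.permutation(len(level_list))
        held = {level_list[i] for i in perm[:n_test_groups]}
        test = [s for s in ids if levels[s] in held]
        train = [s for s in ids if levels[s] not in held]
        splits.append((train, test))
    return splits


# ---------------------------------------------------------------------------
# Fitting and evaluation
# ---------------------------------------------------------------------------

def _design(block: OmicsBlock, sample_ids: Sequence[str]) -> np.ndarray:
    pos = {s: j for j, s in enumerate(block.sample_ids)}
    idx = [pos[s] for s in sample_ids]
    return block.values[:, idx].T  # samples x features


def _dmatrix(x: np.ndarray, feature_ids: list[str],
             y: np.ndarray | None = None) -> xgb.DMatrix:
    return xgb.DMatrix(x, label=y, missing=np.nan, feature_names=feature_ids)


def _train(x: np.ndarray, y: np.ndarray, config: BoostConfig,
           feature_ids: list[str]) -> xgb.Booster:
    dtrain = _dmatrix(x, feature_ids, y)
    return xgb.train(config.xgb_params(x.shape[1]), dtrain,
                     num_boost_round=config.n_rounds)


def _regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return {"r2": r2, "rmse": float(np.sqrt(ss_res / len(y_true)))}


def _classification_metrics(y_true: np.ndarray, prob: np.ndarray) -> dict:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    acc = float(np.mean((prob >= 0.5) == (y_true >= 0.5)))
    ll = float(-np.mean(y_true * np.log(prob) + (1 - y_true) * np.log(1 - prob)))
    return {"accuracy": acc, "log_loss": ll}


def fit(x_block: OmicsBlock, y: OutcomeVector, config: BoostConfig,
        split: SplitSpec, metadata: SampleMetadata | None = None) -> BoostModel:
    """Train boosters over the requested splits and score held-out samples.

    Test R² uses the test-set mean for its total sum of squares and may be
    negative; negative values are reported, not clipped.  Missing predictor
    entries flow to XGBoost's native missing-value routing.
    """
    if config.objective == "logistic" and y.task != "classification":
        raise ValidationError("logistic objective requires a classification outcome")
    if config.objective == "squared-error" and y.task != "regression":
        raise ValidationError("squared-error objective requires a regression outcome")
    common = [s for s in x_block.sample_ids if s in set(y.sample_ids)]
    if not common:
        raise ValidationError("predictor block and outcome share no samples")
    xb = x_block.subset_samples(common)
    yv = y.subset(common)
    splits = make_splits(metadata, split, sample_ids=common)

    rows = []
    split_boosters = []
    y_by_id = dict(zip(yv.sample_ids, yv.y))
    for k, (train_ids, test_ids) in enumerate(splits):
        y_train = np.array([y_by_id[s] for s in train_ids])
        y_test = np.array([y_by_id[s] for s in test_ids])
        if np.all(y_train == y_train[0]):
            raise ValidationError(
                f"split {k}: outcome has zero variance on the training set")
        cfg = replace(config, seed=config.seed + k)
        booster = _train(_design(xb, train_ids), y_train, cfg, xb.feature_ids)
        split_boosters.append(booster)
        pred = booster.predict(_dmatrix(_design(xb, test_ids), xb.feature_ids))
        if yv.task == "regression":
            m = _regression_metrics(y_test, pred)
        else:
            m = _classification_metrics(y_test, pred)
        rows.append({"split": k, "n_train": len(train_ids),
                     "n_test": len(test_ids), **m})

    metrics = pd.DataFrame(rows)
    metric_cols = [c for c in metrics.columns
                   if c not in ("split", "n_train", "n_test")]
    mean_metrics = {c: float(metrics[c].mean()) for c in metric_cols}
    full = _train(_design(xb, common), yv.y, config, xb.feature_ids)
    return BoostModel(full, split_boosters, config, split, list(xb.feature_ids),
                      metrics, mean_metrics, task=yv.task)


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------

DEFAULT_GRID = tuple(itertools.product((50, 100, 200, 500), (2, 3, 4, 6)))


@dataclass
class TuneResult:
    """Selected configuration plus the full cross-validated grid table."""

    config: BoostConfig
    cv_results: pd.DataFrame


def tune(x_block: OmicsBlock, y: OutcomeVector,
         grid: Iterable[tuple[int, int]] = DEFAULT_GRID,
         cv_folds: int | str = 5,
         base_config: BoostConfig | None = None) -> TuneResult:
    """Grid search over (n_rounds, max_depth) by k-fold CV (or LOOCV).

    Selects the grid point with the smallest mean CV RMSE (regression) or
    log-loss (classification); ties break toward smaller ``n_rounds`` then
    smaller ``max_depth``.  ``cv_folds="loo"`` (or ``cv_folds == n``) runs
    leave-one-out CV.
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("tuning grid is empty")
    base = base_config or BoostConfig()
    common = [s for s in x_block.sample_ids if s in set(y.sample_ids)]
    xb = x_block.subset_samples(common)
    yv = y.subset(common)
    n = len(common)
    folds = n if cv_folds == "loo" else int(cv_folds)
    if folds < 2:
        raise ValidationError("cv_folds must be >= 2")
    if folds > n:
        raise ValidationError(f"cv_folds={folds} exceeds sample count {n}")
    rng = np.random.default_rng(base.seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for pos, idx in enumerate(order):
        fold_of[idx] = pos % folds
    x_all = _design(xb, common)
    loss_name = "rmse" if yv.task == "regression" else "log_loss"

    rows = []
    for n_rounds, max_depth in grid:
        cfg = replace(base, n_rounds=n_rounds, max_depth=max_depth)
        losses = []
        for f in range(folds):
            test = fold_of == f
            booster = _train(x_all[~test], yv.y[~test], cfg, xb.feature_ids)
            pred = booster.predict(_dmatrix(x_all[test], xb.feature_ids))
            if yv.task == "regression":
                losses.append(float(np.sqrt(np.mean((yv.y[test] - pred) ** 2))))
            else:
                losses.append(_classification_metrics(yv.y[test], pred)["log_loss"])
        rows.append({"n_rounds": n_rounds, "max_depth": max_depth,
                     f"cv_{loss_name}": float(np.mean(losses))})
    table = pd.DataFrame(rows)
    best = table.sort_values([f"cv_{loss_name}", "n_rounds", "max_depth"],
                             kind="stable").iloc[0]
    chosen = replace(base, n_rounds=int(best["n_rounds"]),
                     max_depth=int(best["max_depth"]))
    return TuneResult(chosen, table)


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

def _margin_predictions(booster: xgb.Booster, dmat: xgb.DMatrix) -> np.ndarray:
    return booster.predict(dmat, output_margin=True)


def shap_values(model: BoostModel, x_block: OmicsBlock,
                booster: xgb.Booster | None = None) -> ShapResult:
    """Tree-path-dependent Shapley attributions for every sample.

    Local accuracy holds exactly: base value plus the attribution row sum
    equals the model's margin prediction (the raw prediction for
    regression, log-odds for classification).
    """
    if x_block.feature_ids != model.feature_ids:
        raise ValidationError(
            "block features do not match the model's training features")
    booster = booster or model.booster
    x = x_block.values.T
    dmat = _dmatrix(x, model.feature_ids)
    contribs = booster.predict(dmat, pred_contribs=True)
    attributions = contribs[:, :-1]
    base = float(np.mean(contribs[:, -1]))
    importance = np.mean(np.abs(attributions), axis=0)
    direction = np.zeros(len(model.feature_ids), dtype=int)
    for j in range(x.shape[1]):
        xs, at = x[:, j], attributions[:, j]
        ok = ~np.isnan(xs)
        if ok.sum() < 3 or np.std(xs[ok]) == 0 or np.std(at[ok]) == 0:
            continue
        r = float(np.corrcoef(xs[ok], at[ok])[0, 1])
        if abs(r) >= DIRECTION_DEAD_ZONE:
            direction[j] = 1 if r > 0 else -1
    idx = pd.Index(model.feature_ids, name="feature")
    return ShapResult(
        pd.DataFrame(attributions, index=x_block.sample_ids, columns=idx),
        base,
        pd.Series(importance, index=idx, name="importance"),
        pd.Series(direction, index=idx, name="direction"),
    )


def rank_features(shap: ShapResult, top_n: int | None = None) -> pd.DataFrame:
    """Features sorted by mean |attribution| descending, ties by id."""
    if top_n is not None and top_n < 1:
        raise ValidationError("top_n must be >= 1")
    table = pd.DataFrame({"importance": shap.importance,
                          "direction": shap.direction})
    table = (table.reset_index()
             .sort_values(["importance", "feature"],
                          ascending=[False, True], kind="stable")
             .reset_index(drop=True))
    return table if top_n is None else table.head(top_n)


# ---------------------------------------------------------------------------
# Boruta-SHAP feature selection
# ---------------------------------------------------------------------------

def boruta_shap(x_block: OmicsBlock, y: OutcomeVector,
                config: BoostConfig | None = None,
                n_iter: int = 20, alpha: float = 0.05) -> pd.DataFrame:
    """Shadow-feature selection with Shapley importances.

    Each iteration appends a column-permuted shadow copy of every feature,
    fits the model on the augmented matrix, and credits a real feature with
    a hit when its mean |attribution| exceeds the best shadow's.  Decisions
    come from a two-sided binomial test of the hit count against
    Binomial(n_iter, 0.5) at level ``alpha``: significantly more hits than
    chance -> confirmed, significantly fewer -> rejected, else tentative.
    """
    if n_iter < 5:
        raise ValidationError("boruta_shap needs n_iter >= 5")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    config = config or BoostConfig()
    common = [s for s in x_block.sample_ids if s in set(y.sample_ids)]
    xb = x_block.subset_samples(common)
    yv = y.subset(common)
    if len(common) < 10:
        raise ValidationError(
            f"too few samples ({len(common)}) to fit shadow models")
    x = _design(xb, common)
    n, p = x.shape
    names = xb.feature_ids + [f"shadow:{f}" for f in xb.feature_ids]
    rng = np.random.default_rng(config.seed)
    hits = np.zeros(p, dtype=int)
    for it in range(n_iter):
        shadow = np.empty_like(x)
        for j in range(p):
            shadow[:, j] = x[rng.permutation(n), j]
        aug = np.hstack([x, shadow])
        cfg = replace(config, seed=config.seed + 1000 + it)
        booster = _train(aug, yv.y, cfg, names)
        contribs = booster.predict(_dmatrix(aug, names), pred_contribs=True)
        imp = np.mean(np.abs(contribs[:, :-1]), axis=0)
        hits += imp[:p] > imp[p:].max()
    decisions = []
    for j, f in enumerate(xb.feature_ids):
        pval = stats.binomtest(int(hits[j]), n_iter, 0.5).pvalue
        if pval <= alpha and hits[j] > n_iter / 2:
            decision = "confirmed"
        elif pval <= alpha and hits[j] < n_iter / 2:
            decision = "rejected"
        else:
            decision = "tentative"
        decisions.append({"feature": f, "hits": int(hits[j]),
                          "n_iter": n_iter, "p_value": float(pval),
                          "decision": decision})
    return pd.DataFrame(decisions)
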