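"""Monotonic-constraint workflow and pairwise interaction analysis.

Domain knowledge about how a feature relates to the outcome is exchanged
as a two-column table — ``feature`` and ``final_association`` with values
+1 (known positive), -1 (known negative) or 0 (unknown).  Directions can
also be derived from a fitted model's Shapley attributions, or drawn at
random for unknowns (the null condition against which informed constraints
are compared).  The merged table is injected into the booster as per-
feature monotonic constraints, forcing the fitted response to be
non-decreasing (+1) or non-increasing (-1) in each constrained feature.

Pairwise feature interactions come from the tree ensemble's Shapley
interaction values: a samples x features x features tensor whose entries
(with self terms and the base value) reconstruct each prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .io import OmicsBlock, OutcomeVector, SampleMetadata, ValidationError, logger
from .predict import (BoostConfig, BoostModel, ShapResult, SplitSpec,
                      _design, _dmatrix, fit)

VALID_ASSOCIATIONS = (-1, 0, 1)


@dataclass
class ConstraintTable:
    """Feature -> {-1, 0, +1} monotone directions, with per-row provenance."""

    table: pd.DataFrame  # columns: feature, final_association, provenance

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "feature" not in t.columns or "final_association" not in t.columns:
            raise ValidationError(
                "constraint table needs columns 'feature' and 'final_association'")
        if "provenance" not in t.columns:
            t["provenance"] = "user"
        t["feature"] = t["feature"].astype(str)
        try:
            t["final_association"] = t["final_association"].astype(int)
        except (TypeError, ValueError):
            raise ValidationError(
                "final_association must be integer -1, 0 or +1") from None
        bad = ~t["final_association"].isin(VALID_ASSOCIATIONS)
        if bad.any():
            raise ValidationError(
                f"invalid final_association values: "
                f"{t.loc[bad, 'final_association'].unique().tolist()}")
        if t["feature"].duplicated().any():
            dups = t.loc[t["feature"].duplicated(), "feature"].tolist()
            raise ValidationError(f"duplicate constraint features: {dups[:5]}")
        self.table = t.reset_index(drop=True)

    def association(self) -> pd.Series:
        return self.table.set_index("feature")["final_association"]

    @classmethod
    def from_mapping(cls, mapping: dict[str, int],
                     provenance: str = "user") -> "ConstraintTable":
        return cls(pd.DataFrame({
            "feature": list(mapping), "final_association": list(mapping.values()),
            "provenance": provenance}))


def read_constraints(path: str | Path) -> ConstraintTable:
    return ConstraintTable(pd.read_csv(path))


def write_constraints(table: ConstraintTable, path: str | Path,
                      include_provenance: bool = True) -> None:
    cols = ["feature", "final_association"] + \
        (["provenance"] if include_provenance else [])
    table.table[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Building constraint tables
# ---------------------------------------------------------------------------

def derive_constraints(shap: ShapResult) -> ConstraintTable:
    """Directions from a model's Shapley attributions.

    Each feature's association is the sign of the correlation between its
    values and its attributions (zero inside the dead zone), i.e. the
    model's own estimate of the feature-outcome direction.
    """
    return ConstraintTable(pd.DataFrame({
        "feature": shap.direction.index.astype(str),
        "final_association": shap.direction.to_numpy(),
        "provenance": "shap_derived"}))


def randomize_constraints(table: ConstraintTable, seed: int) -> ConstraintTable:
    """Replace every unknown (0) association with a uniform +/-1 draw."""
    rng = np.random.default_rng(seed)
    t = table.table.copy()
    zero = t["final_association"] == 0
    t.loc[zero, "final_association"] = rng.choice((-1, 1), size=int(zero.sum()))
    t.loc[zero, "provenance"] = "random"
    return ConstraintTable(t)


def merge_constraints(user: ConstraintTable,
                      derived: ConstraintTable) -> ConstraintTable:
    """Union of two tables; on nonzero conflicts the user's value wins."""
    u = user.table.set_index("feature")
    d = derived.table.set_index("feature")
    features = list(dict.fromkeys(list(u.index) + list(d.index)))
    rows = []
    for f in features:
        uv = int(u.loc[f, "final_association"]) if f in u.index else 0
        dv = int(d.loc[f, "final_association"]) if f in d.index else 0
        if uv != 0:
            if dv != 0 and dv != uv:
                logger.info("constraint conflict on %r: user %+d overrides "
                            "derived %+d", f, uv, dv)
            value, prov = uv, str(u.loc[f, "provenance"]) if f in u.index else "user"
        elif dv != 0:
            value, prov = dv, str(d.loc[f, "provenance"])
        else:
            value = 0
            prov = str((u if f in u.index else d).loc[f, "provenance"])
        rows.append({"feature": f, "final_association": value, "provenance": prov})
    return ConstraintTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Constrained fitting
# ---------------------------------------------------------------------------

def monotone_vector(table: ConstraintTable,
                    feature_ids: list[str]) -> tuple[int, ...]:
    """Per-feature monotone directions in block order; unlisted -> 0."""
    assoc = table.association()
    absent = [f for f in assoc.index if f not in set(feature_ids)]
    if absent:
        logger.warning("constraints reference %d feature(s) absent from the "
                       "block (ignored): %s", len(absent), absent[:5])
    return tuple(int(assoc.get(f, 0)) for f in feature_ids)


def fit_constrained(x_block: OmicsBlock, y: OutcomeVector, config: BoostConfig,
                    table: ConstraintTable, split: SplitSpec,
                    metadata: SampleMetadata | None = None) -> BoostModel:
    """Fit under the table's monotonic constraints; metrics as in ``fit``."""
    vec = monotone_vector(table, x_block.feature_ids)
    model = fit(x_block, y, replace(config, monotone=vec), split, metadata)
    model.constraint_table = table
    return model


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    """Pairwise Shapley interaction summary for one model.

    ``matrix`` is the symmetric features x features mean |interaction|
    summary (diagonal = main-effect magnitudes); ``pairs`` ranks the
    off-diagonal pairs; ``tensor`` keeps the per-sample interaction values
    (samples x features x features, bias row/column stripped).
    """

    matrix: pd.DataFrame
    pairs: pd.DataFrame
    tensor: np.ndarray
    base_value: float


def interactions(model: BoostModel, x_block: OmicsBlock,
                 known: list[str] | None = None,
                 predicted: list[str] | None = None) -> InteractionResult:
    """Shapley interaction values for every sample and feature pair.

    When ``known`` and ``predicted`` feature lists are given, ``pairs``
    additionally flags the known x predicted pairs so candidate-gene
    hypotheses can be read off directly.
    """
    if x_block.feature_ids != model.feature_ids:
        raise ValidationError(
            "block features do not match the model's training features")
    feature_set = set(model.feature_ids)
    for name, lst in (("known", known), ("predicted", predicted)):
        unknown = [f for f in (lst or []) if f not in feature_set]
        if unknown:
            raise ValidationError(
                f"{name} feature(s) not in the model: {unknown[:5]}")
    dmat = _dmatrix(x_block.values.T, model.feature_ids)
    inter = model.booster.predict(dmat, pred_interactions=True)
    base = float(np.mean(inter[:, -1, -1]))
    tensor = inter[:, :-1, :-1]
    summary = np.mean(np.abs(tensor), axis=0)
    summary = 0.5 * (summary + summary.T)  # enforce exact symmetry
    idx = pd.Index(model.feature_ids, name="feature")
    matrix = pd.DataFrame(summary, index=idx, columns=idx)

    known_set, pred_set = set(known or []), set(predicted or [])
    rows = []
    p = len(model.feature_ids)
    for i in range(p):
        for j in range(i + 1, p):
            fi, fj = model.feature_ids[i], model.feature_ids[j]
            rows.append({
                "feature_a": fi, "feature_b": fj,
                "mean_abs_interaction": float(summary[i, j]),
                "known_x_predicted": (
                    (fi in known_set and fj in pred_set)
                    or (fj in known_set and fi in pred_set)),
            })
    pairs = (pd.DataFrame(rows)
             .sort_values(["mean_abs_interaction", "feature_a", "feature_b"],
                          ascending=[False, True, True], kind="stable")
             .reset_index(drop=True))
    return InteractionResult(matrix, pairs, tensor, base)


def interaction_null(model: BoostModel, x_block: OmicsBlock,
                     y: OutcomeVector, n_perm: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """Optional permutation null for interaction scores.

    Refits the model ``n_perm`` times on y-permuted data and reports, per
    observed pair, the fraction of null fits whose maximum off-diagonal
    interaction meets or exceeds the observed score (a max-statistic
    family-wise p-value).
    """
    from .predict import _train  # local import to keep the surface tidy
    rng = np.random.default_rng(seed)
    obs = interactions(model, x_block)
    x = x_block.values.T
    p = len(model.feature_ids)
    null_max = np.empty(n_perm)
    yy = y.subset(x_block.sample_ids).y
    for b in range(n_perm):
        perm = rng.permutation(len(yy))
        cfg = replace(model.config, seed=model.config.seed + 5000 + b,
                      monotone=None)
        booster = _train(x, yy[perm], cfg, model.feature_ids)
        inter = booster.predict(_dmatrix(x, model.feature_ids),
                                pred_interactions=True)[:, :-1, :-1]
        summary = np.mean(np.abs(inter), axis=0)
        off = summary[~np.eye(p, dtype=bool)]
        null_max[b] = off.max() if off.size else 0.0
    out = obs.pairs.copy()
    out["p_value"] = [
        float((np.sum(null_max >= s) + 1) / (n_perm + 1))
        for s in out["mean_abs_interaction"]]
    return out
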