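"""Per-block and integrated PCA with ANOVA of component scores.

Individual blocks are analysed by a samples-as-observations PCA on
feature-centered (optionally unit-variance-scaled) data.  For the
integrated analysis each block is first standardized to a unit sum of
squares — centered, then divided by its Frobenius norm — so every block
contributes the same total deviation, and the blocks are concatenated
along the feature axis before a single PCA without further per-feature
scaling.  Sources of variance are then located by one-way ANOVA of the
component scores against metadata factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsBlock, SampleMetadata, ValidationError


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of one PCA.

    ``scores`` is samples x components, ``loadings`` features x components
    (orthonormal columns), ``var_fraction`` sums to 1 over all components.
    For an integrated PCA ``block_of_feature`` labels each loading row with
    its source block.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_fraction: np.ndarray
    block_of_feature: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": self.scores.columns,
            "var_fraction": self.var_fraction,
            "cumulative": np.cumsum(self.var_fraction),
        })


@dataclass
class ScoreAnova:
    """One-way ANOVA of one component's scores against one factor."""

    component: str
    factor: str
    F: float
    p: float
    df: tuple[int, int]


def block_scale_unit_ss(block: OmicsBlock) -> OmicsBlock:
    """Center features and rescale the whole block to unit sum of squares.

    After scaling the block's Frobenius norm is exactly 1, so blocks of
    wildly different magnitudes contribute comparable total deviations to a
    concatenated analysis.
    """
    x = block.values
    if np.isnan(x).any():
        raise ValidationError(
            f"block '{block.name}' has missing entries; filter or complete "
            "them before variance analysis")
    centered = x - x.mean(axis=1, keepdims=True)
    ss = float(np.sum(centered ** 2))
    if ss == 0.0:
        raise ValidationError(
            f"block '{block.name}' has zero total deviation (all features constant)")
    return block.with_values(centered / np.sqrt(ss))


def _pca_matrix(x: np.ndarray, sample_ids, feature_ids,
                center: bool, scale_features: bool,
                feature_names_for_errors: list[str]) -> PcaResult:
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale_features:
        sd = x.std(axis=0, ddof=1)
        dead = sd == 0
        if dead.any():
            bad = [feature_names_for_errors[i] for i in np.flatnonzero(dead)[:5]]
            raise ValidationError(
                f"constant features cannot be unit-variance scaled: {bad}; "
                "filter them or disable feature scaling")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign convention: largest-magnitude loading positive
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    total = float(np.sum(s ** 2))
    var_fraction = s ** 2 / total if total > 0 else np.zeros_like(s)
    comps = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=sample_ids, columns=comps)
    loadings = pd.DataFrame(vt.T, index=feature_ids, columns=comps)
    return PcaResult(scores, loadings, var_fraction)


def pca(block: OmicsBlock, scale_features: bool = True) -> PcaResult:
    """PCA of one block with samples as observations.

    Features are centered across samples; by default each feature is also
    scaled to unit variance (the conventional choice for a single assay
    whose features live on heterogeneous scales).  Explained-variance
    fractions come from the squared singular values.
    """
    if block.n_samples < 2:
        raise ValidationError("PCA requires at least 2 samples")
    if np.isnan(block.values).any():
        raise ValidationError(
            f"block '{block.name}' has missing entries; PCA has no native "
            "missing-value contract — filter features or mean-complete "
            "explicitly upstream")
    return _pca_matrix(block.values.T, block.sample_ids, block.feature_ids,
                       center=True, scale_features=scale_features,
                       feature_names_for_errors=block.feature_ids)


def integrated_pca(blocks: list[OmicsBlock]) -> PcaResult:
    """Joint PCA of several unit-sum-of-squares-scaled blocks.

    Each block is centered and scaled to unit total sum of squares, the
    blocks are concatenated feature-wise, and one PCA is run without
    per-feature scaling; loadings carry their source-block label.
    """
    if not blocks:
        raise ValidationError("integrated_pca needs at least one block")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValidationError(
                f"blocks are not sample-aligned ('{blocks[0].name}' vs "
                f"'{b.name}'); run align_samples first")
    scaled = [block_scale_unit_ss(b) for b in blocks]
    values = np.vstack([b.values for b in scaled])
    feature_ids = [f"{b.name}:{f}" for b in scaled for f in b.feature_ids]
    labels = [b.name for b in scaled for _ in b.feature_ids]
    result = _pca_matrix(values.T, ref, feature_ids, center=True,
                         scale_features=False,
                         feature_names_for_errors=feature_ids)
    result.block_of_feature = labels
    return result


def anova_scores(pca_result: PcaResult, metadata: SampleMetadata,
                 factors: list[str],
                 components: list[str] | None = None) -> list[ScoreAnova]:
    """One-way ANOVA of component scores against each metadata factor."""
    components = components or list(pca_result.scores.columns)
    meta = metadata.subset([str(s) for s in pca_result.scores.index])
    out: list[ScoreAnova] = []
    for factor in factors:
        levels = meta.factor(factor)
        groups_idx = {lv: np.flatnonzero((levels == lv).to_numpy())
                      for lv in pd.unique(levels)}
        k = len(groups_idx)
        n = len(levels)
        if k < 2:
            raise ValidationError(
                f"factor {factor!r} has a single level; ANOVA undefined")
        if n - k == 0:
            raise ValidationError(
                f"factor {factor!r} has only singleton groups "
                "(zero within-group degrees of freedom)")
        for comp in components:
            scores = pca_result.scores[comp].to_numpy()
            samples = [scores[idx] for idx in groups_idx.values()]
            with np.errstate(invalid="ignore", divide="ignore"):
                f_stat, p = stats.f_oneway(*samples)
            if not np.isfinite(f_stat):  # zero between- and within-variance
                f_stat, p = 0.0, 1.0
            out.append(ScoreAnova(comp, factor, float(f_stat), float(p),
                                  (k - 1, n - k)))
    return out


def anova_table(results: list[ScoreAnova]) -> pd.DataFrame:
    return pd.DataFrame([{
        "component": r.component, "factor": r.factor, "F": r.F, "p": r.p,
        "df_between": r.df[0], "df_within": r.df[1],
    } for r in results])
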