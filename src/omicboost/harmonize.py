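"""Count normalization and spectral preprocessing.

Count normalization follows the median-of-log-ratios scheme: for each
sample j a scaling factor

    s_j = exp( median_{i in G} [ ln x_ij - (1/n) * sum_k ln x_ik ] )

is computed over the set G of stably expressed genes — those with strictly
positive counts in every sample, the only genes whose mean log-expression
is finite under a natural log of raw counts (no pseudocounts).  Normalized
counts are x_ij / s_j.  The median makes the factor robust to high-count
outliers; the scheme corrects sequencing-depth and composition differences
between samples.

Spectral preprocessing targets ATR-FTIR absorbance spectra: selection of a
wavenumber range, asymmetric-least-squares (ALS) baseline subtraction, and
Savitzky-Golay polynomial smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .io import OmicsBlock, ValidationError, logger


# ---------------------------------------------------------------------------
# Count normalization
# ---------------------------------------------------------------------------

@dataclass
class ScalingFactors:
    """Per-sample scaling factors s_j and the gene set G that defined them."""

    sample_ids: list[str]
    s: np.ndarray
    genes_used: list[str]

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (len(self.sample_ids),):
            raise ValidationError("one scaling factor per sample required")
        if not np.all(self.s > 0):
            raise ValidationError("scaling factors must be strictly positive")
        if not self.genes_used:
            raise ValidationError("genes_used must be non-empty")


def scaling_factors(block: OmicsBlock) -> ScalingFactors:
    """Median-of-log-ratios scaling factors for a raw count block.

    G is the set of genes with strictly positive, non-missing counts in
    every sample; an even-sized median averages the two central values.
    """
    x = block.values
    finite = ~np.isnan(x)
    if np.any(x[finite] < 0):
        raise ValidationError("raw counts must be non-negative")
    in_g = np.all(finite & (x > 0), axis=1)
    if not in_g.any():
        raise ValidationError(
            "no gene has strictly positive counts in all samples; filter "
            "all-zero/sparse genes or supply raw counts")
    logx = np.log(x[in_g, :])
    deviations = logx - logx.mean(axis=1, keepdims=True)
    s = np.exp(np.median(deviations, axis=0))
    genes = [block.feature_ids[i] for i in np.flatnonzero(in_g)]
    return ScalingFactors(list(block.sample_ids), s, genes)


def normalize_counts(block: OmicsBlock, factors: ScalingFactors) -> OmicsBlock:
    """Divide every gene's counts by its sample's scaling factor.

    All genes are normalized, including those outside G; missing entries
    stay missing.
    """
    if factors.sample_ids != block.sample_ids:
        raise ValidationError(
            "scaling factors were computed for different samples than the block")
    return block.with_values(block.values / factors.s[np.newaxis, :])


class FilterResult(NamedTuple):
    block: OmicsBlock
    kept: int
    dropped: int


def filter_low_expression(block: OmicsBlock, threshold: float) -> FilterResult:
    """Keep features whose maximum value across samples is >= threshold.

    Missing entries are ignored when taking the maximum; a feature that is
    missing everywhere is dropped (its observed maximum is undefined).
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    x = block.values
    maxima = np.where(np.isnan(x), -np.inf, x).max(axis=1)
    keep = maxima >= threshold
    kept, dropped = int(keep.sum()), int((~keep).sum())
    if kept == 0:
        logger.warning("filter_low_expression: threshold %g removed every "
                       "feature of block '%s'", threshold, block.name)
    return FilterResult(block.subset_features(keep), kept, dropped)


# ---------------------------------------------------------------------------
# Spectral preprocessing
# ---------------------------------------------------------------------------

@dataclass
class SpectralParams:
    """Parameters for FTIR-style spectral preprocessing.

    range : (high, low) wavenumber bounds in cm^-1 (order irrelevant;
        normalized internally).  Default 4000-400 cm^-1, the usual ATR
        acquisition window.
    baseline_method : only ``"asls"`` (asymmetric least squares) is built
        in; ``baseline_lambda`` is the smoothness penalty, ``baseline_p``
        the asymmetry (weights points above the baseline by p, below by
        1-p), ``baseline_iterations`` the number of reweighting passes.
    sg_window / sg_polyorder : Savitzky-Golay window length (odd, points)
        and polynomial order; defaults 11 / 3 are conventional for 4 cm^-1
        resolution spectra.
    """

    range: tuple[float, float] = (4000.0, 400.0)
    baseline_method: str = "asls"
    baseline_lambda: float = 1e5
    baseline_p: float = 0.01
    baseline_iterations: int = 10
    sg_window: int = 11
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValidationError(
                f"sg_window must be odd and > sg_polyorder "
                f"(got window={self.sg_window}, polyorder={self.sg_polyorder})")
        if self.baseline_method != "asls":
            raise ValidationError(
                f"unknown baseline method {self.baseline_method!r}")


def select_spectral_range(block: OmicsBlock,
                          bounds: tuple[float, float]) -> OmicsBlock:
    """Restrict a spectral block to wavenumbers within [low, high] inclusive."""
    if block.feature_axis is None:
        raise ValidationError(
            f"block '{block.name}' has no feature axis (wavenumbers)")
    diffs = np.diff(block.feature_axis)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValidationError("feature axis must be strictly monotone")
    low, high = sorted(float(b) for b in bounds)
    keep = (block.feature_axis >= low) & (block.feature_axis <= high)
    return block.subset_features(keep)


def _asls_baseline(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    """Eilers asymmetric-least-squares baseline of one spectrum."""
    m = len(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(m, m - 2))
    penalty = lam * (d @ d.T)
    w = np.ones(m)
    z = y
    for _ in range(n_iter):
        lhs = sparse.diags(w) + penalty
        z = spsolve(lhs.tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(block: OmicsBlock, params: SpectralParams | None = None,
                     return_baselines: bool = False):
    """Subtract a smooth ALS-estimated baseline from each sample's spectrum.

    Returns the corrected block, or ``(corrected, baselines)`` when
    ``return_baselines`` is set (baselines as a block, for plotting).
    """
    params = params or SpectralParams()
    x = block.values
    if np.isnan(x).any():
        raise ValidationError("spectra must not contain missing entries")
    if block.n_features < 10:
        raise ValidationError(
            f"spectrum too short for baseline estimation ({block.n_features} points)")
    baselines = np.empty_like(x)
    for j in range(block.n_samples):
        baselines[:, j] = _asls_baseline(
            x[:, j], params.baseline_lambda, params.baseline_p,
            params.baseline_iterations)
    corrected = block.with_values(x - baselines)
    if return_baselines:
        return corrected, block.with_values(baselines)
    return corrected


def savgol_smooth(block: OmicsBlock,
                  params: SpectralParams | None = None) -> OmicsBlock:
    """Savitzky-Golay smooth each sample's spectrum.

    Edges are handled by fitting the terminal windows' polynomials
    (``mode="interp"``), so polynomial signals up to ``sg_polyorder`` pass
    through unchanged everywhere including endpoints.
    """
    params = params or SpectralParams()
    if params.sg_window > block.n_features:
        raise ValidationError(
            f"sg_window {params.sg_window} exceeds spectrum length "
            f"{block.n_features}")
    if np.isnan(block.values).any():
        raise ValidationError("spectra must not contain missing entries")
    smoothed = savgol_filter(block.values, params.sg_window,
                             params.sg_polyorder, axis=0, mode="interp")
    return block.with_values(smoothed)
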