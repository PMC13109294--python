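"""Synthetic multi-omics generator with known ground truth.

The generator emulates the structure of a multi-platform stress-course
experiment: several omics blocks (a positive, right-skewed counts block, a
spectra-like continuous block, a small trait panel) measured on the same
samples; samples organised into replicate groups nested in a two-level
treatment factor crossed with time; shared latent factors inducing
cross-block covariance; a continuous outcome linked monotonically to a
small set of planted features; block-specific noise; optional missing
entries.  A separate routine produces FTIR-like absorbance spectra as
Gaussian peaks riding on a smooth polynomial baseline over a descending
4000-400 cm^-1 wavenumber grid.

Everything is reproducible from the design seed, and the returned truth
record carries whatever downstream checks need (planted ids and
directions, clean signals, per-sample peak heights).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import OmicsBlock, OutcomeVector, SampleMetadata, ValidationError


@dataclass
class SimDesign:
    """Study design for the multi-omics simulator.

    Defaults follow a small two-condition time-course with 2-3 plants per
    replicate group: 48 samples in 8 replicate groups (4 per condition),
    3 shared latent factors, a counts block plus two continuous blocks,
    5 planted outcome-linked features with alternating directions, and a
    moderate outcome noise of 0.3 signal SDs.
    """

    n_samples: int = 48
    n_replicate_groups: int = 8
    block_features: Mapping[str, int] = field(
        default_factory=lambda: {"transcriptome": 200, "ftir": 100,
                                 "phenome": 20})
    counts_block: str | None = "transcriptome"
    n_latent: int = 3
    planted_block: str = "transcriptome"
    n_planted: int = 5
    planted_directions: Sequence[int] | None = None
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"transcriptome": 0.5, "ftir": 0.3,
                                 "phenome": 0.5})
    replicate_sd: float = 0.5
    treatment_effect: float = 2.0
    outcome_noise_sd: float = 0.3       # relative to the clean signal's SD
    outcome_nonlinearity: float = 0.3   # cubic share of the monotone link
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.n_samples < 2 * self.n_replicate_groups:
            raise ValidationError(
                "need at least two samples per replicate group")
        if self.planted_block not in self.block_features:
            raise ValidationError(
                f"planted_block {self.planted_block!r} is not a block")
        if self.n_planted > self.block_features[self.planted_block]:
            raise ValidationError("more planted features than block features")
        if self.planted_directions is not None:
            dirs = tuple(int(d) for d in self.planted_directions)
            if len(dirs) != self.n_planted or any(d not in (-1, 1) for d in dirs):
                raise ValidationError(
                    "planted_directions must be n_planted values in {-1, +1}")
            self.planted_directions = dirs
        if self.counts_block is not None \
                and self.counts_block not in self.block_features:
            raise ValidationError(
                f"counts_block {self.counts_block!r} is not a block")
        if self.outcome_nonlinearity < 0:
            raise ValidationError("outcome_nonlinearity must be >= 0")


@dataclass
class SimData:
    blocks: list[OmicsBlock]
    metadata: SampleMetadata
    outcome: OutcomeVector
    truth: dict


def _feature_ids(block: str, p: int) -> list[str]:
    return [f"{block}_{i:04d}" for i in range(p)]


def simulate_multiomics(design: SimDesign) -> SimData:
    """Draw one dataset from the design; bit-reproducible from its seed."""
    rng = np.random.default_rng(design.seed)
    n, g = design.n_samples, design.n_replicate_groups
    sample_ids = [f"S{i:03d}" for i in range(n)]
    group = np.arange(n) % g
    condition = np.where(group < g // 2, "control", "treatment")
    time = (np.arange(n) // g) % max(1, n // g)

    metadata = SampleMetadata(pd.DataFrame({
        "condition": condition,
        "time": [f"T{t}" for t in time],
        "replicate": [f"R{gr}" for gr in group],
    }, index=sample_ids))

    # latent factor scores with treatment and replicate-group effects
    z = rng.standard_normal((design.n_latent, n))
    z[0] += design.treatment_effect * (condition == "treatment")
    group_effects = design.replicate_sd * rng.standard_normal(
        (design.n_latent, g))
    z += group_effects[:, group]

    blocks: list[OmicsBlock] = []
    latent_values: dict[str, np.ndarray] = {}
    planted_idx = np.arange(design.n_planted)
    for name, p in design.block_features.items():
        loadings = rng.standard_normal((p, design.n_latent)) / np.sqrt(
            design.n_latent)
        noise = design.noise_sd.get(name, 0.5) * rng.standard_normal((p, n))
        signal = loadings @ z + noise
        if name == design.planted_block:
            # planted features carry their own signal, independent of the
            # shared latents, so the remaining features are pure noise with
            # respect to the outcome (proxies would otherwise dilute any
            # feature-recovery readout)
            own = rng.standard_normal((design.n_planted, n)) \
                + design.replicate_sd * rng.standard_normal(
                    (design.n_planted, g))[:, group]
            signal[planted_idx, :] = own \
                + design.noise_sd.get(name, 0.5) * rng.standard_normal(
                    (design.n_planted, n))
        latent_values[name] = signal
        if name == design.counts_block:
            values = np.exp(3.0 + signal)  # positive, right-skewed counts
        else:
            values = signal
        axis = None
        if name == "ftir":
            axis = np.linspace(4000.0, 400.0, p)
        blocks.append(OmicsBlock(name, _feature_ids(name, p), sample_ids,
                                 values, axis))

    # monotone outcome link on planted features (underlying scale, which is
    # log-scale for the counts block — exp is monotone, so the link is
    # monotone in the observed values too)
    directions = (design.planted_directions
                  or tuple((-1) ** i for i in range(design.n_planted)))
    planted_ids = [_feature_ids(design.planted_block,
                                design.block_features[design.planted_block])[i]
                   for i in planted_idx]
    base = latent_values[design.planted_block][planted_idx, :]
    zstd = (base - base.mean(axis=1, keepdims=True)) / \
        base.std(axis=1, keepdims=True)
    link = zstd + design.outcome_nonlinearity * zstd ** 3
    clean = np.asarray(directions, dtype=float) @ link
    noise = design.outcome_noise_sd * clean.std() * rng.standard_normal(n)
    y = OutcomeVector(sample_ids, clean + noise, "regression")

    if design.missing_rate > 0:
        for b in blocks:
            mask = rng.random(b.values.shape) < design.missing_rate
            b.values[mask] = np.nan

    truth = {
        "planted_features": dict(zip(planted_ids, directions)),
        "latent_scores": z,
        "group_effects": group_effects,
        "clean_outcome": clean,
        "outcome_noise_sd_abs": float(design.outcome_noise_sd * clean.std()),
    }
    return SimData(blocks, metadata, y, truth)


def simulate_outcome_labels(sim: SimData) -> OutcomeVector:
    """Binary labels from the median split of the clean outcome.

    With separation driven by the clean signal the two classes are
    noise-free, giving a perfectly learnable classification task.
    """
    clean = sim.truth["clean_outcome"]
    labels = (clean > np.median(clean)).astype(float)
    return OutcomeVector(sim.outcome.sample_ids, labels, "classification")


def simulate_trait_panel(n_samples: int, group_sizes: Sequence[int],
                         within_r: float = 0.95, seed: int = 0
                         ) -> tuple[OmicsBlock, dict]:
    """A trait panel with planted correlation groups.

    Traits in the same group share one latent with correlation
    ``sqrt(within_r)`` loading (pairwise |r| ~= within_r); different groups
    use independent latents (between-group |r| ~= 0).  Signs alternate
    within groups so the panel also exercises sign-blind distances.
    """
    if not (0 < within_r < 1):
        raise ValidationError("within_r must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows, names, truth_groups = [], [], {}
    for gi, size in enumerate(group_sizes):
        latent = rng.standard_normal(n_samples)
        for t in range(size):
            sign = (-1) ** t
            trait = sign * (np.sqrt(within_r) * latent
                            + np.sqrt(1 - within_r)
                            * rng.standard_normal(n_samples))
            name = f"trait_g{gi}_{t}"
            rows.append(trait)
            names.append(name)
            truth_groups[name] = gi
    block = OmicsBlock("phenome", names,
                       [f"S{i:03d}" for i in range(n_samples)],
                       np.asarray(rows))
    return block, {"group_of_trait": truth_groups,
                   "n_groups": len(group_sizes)}


def simulate_spectra(n_samples: int, n_points: int = 901,
                     peaks: Sequence[tuple[float, float, float]] = (
                         (2920.0, 40.0, 1.0),
                         (1650.0, 30.0, 0.8),
                         (1050.0, 50.0, 1.2)),
                     baseline: Sequence[float] = (0.3, 0.15, -0.1),
                     noise_sd: float = 0.003,
                     height_jitter: float = 0.1,
                     seed: int = 0) -> tuple[OmicsBlock, dict]:
    """FTIR-like spectra: Gaussian peaks + polynomial baseline + noise.

    The wavenumber axis descends from 4000 to 400 cm^-1.  ``baseline`` are
    polynomial coefficients (highest degree first) over the normalized
    coordinate u in [0, 1].  Per-sample peak heights are jittered by
    ``height_jitter`` (relative); the truth record returns the clean peak
    component, the baselines, and the realised apex heights.
    """
    if n_points < 50:
        raise ValidationError("need at least 50 spectral points")
    rng = np.random.default_rng(seed)
    axis = np.linspace(4000.0, 400.0, n_points)
    u = (4000.0 - axis) / 3600.0
    base = np.polyval(list(baseline), u)
    clean_peaks = np.zeros((n_points, n_samples))
    heights = np.zeros((len(peaks), n_samples))
    for k, (center, width, height) in enumerate(peaks):
        profile = np.exp(-0.5 * ((axis - center) / width) ** 2)
        h = height * (1.0 + height_jitter * rng.uniform(-1, 1, n_samples))
        heights[k] = h
        clean_peaks += profile[:, None] * h[None, :]
    values = clean_peaks + base[:, None] \
        + noise_sd * rng.standard_normal((n_points, n_samples))
    block = OmicsBlock(
        "ftir", [f"{w:.1f}" for w in axis],
        [f"S{i:03d}" for i in range(n_samples)], values, axis)
    truth = {"axis": axis, "baseline": base, "clean_peaks": clean_peaks,
             "peak_centers": [p[0] for p in peaks], "peak_heights": heights}
    return block, truth
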