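"""Reduction of a correlated phenotype panel to uncorrelated representatives.

High-throughput phenotyping platforms emit hundreds of partially redundant
traits.  The reduction proceeds in three steps: (1) agglomerative
clustering of z-scored traits under the sign-blind correlation distance
1 - |Pearson r| with average linkage; (2) choice of the smallest cluster
count k such that, for every cluster, the first principal component of its
member traits explains at least a threshold fraction (default 50%) of
their variance — i.e. each cluster is essentially co-linear; (3) one
representative per cluster, the trait with the largest absolute PC1
loading.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import OmicsBlock, ValidationError, logger


@dataclass
class TraitDendrogram:
    """Agglomerative dendrogram over traits plus the z-scored trait matrix."""

    linkage_matrix: np.ndarray
    trait_ids: list[str]
    zscores: np.ndarray  # traits x samples


@dataclass
class TraitClustering:
    """A cut of the trait dendrogram with its co-linearity diagnostics."""

    k: int
    assignment: dict[str, int]
    pc1_fraction: dict[int, float]
    representatives: dict[int, str] | None = None


def _zscore_traits(block: OmicsBlock) -> np.ndarray:
    x = block.values
    if np.isnan(x).any():
        raise ValidationError("trait matrix must not contain missing entries")
    sd = x.std(axis=1, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [block.feature_ids[i] for i in dead[:5]]
        raise ValidationError(
            f"constant trait(s) have undefined correlation: {names}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def cluster_traits(block: OmicsBlock, linkage_method: str = "average",
                   distance: str = "abs_correlation") -> TraitDendrogram:
    """Build the trait dendrogram.

    Default distance is 1 - |Pearson r| (sign-blind, since anti-correlated
    traits are just as redundant as correlated ones), with average linkage.
    """
    if block.n_features < 2:
        raise ValidationError("clustering needs at least 2 traits")
    z = _zscore_traits(block)
    r = np.corrcoef(z)
    if distance == "abs_correlation":
        d = 1.0 - np.abs(r)
    elif distance == "correlation":
        d = 1.0 - r
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    np.fill_diagonal(d, 0.0)
    condensed = squareform(np.clip(d, 0.0, None), checks=False)
    z_link = linkage(condensed, method=linkage_method)
    return TraitDendrogram(z_link, list(block.feature_ids), z)


def _pc1_stats(zscores: np.ndarray) -> tuple[float, np.ndarray]:
    """PC1 variance fraction and loadings of a traits x samples submatrix."""
    x = zscores.T  # samples x traits
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s ** 2))
    frac = float(s[0] ** 2 / total) if total > 0 else 1.0
    return frac, vt[0]


def _clusters_at(dend: TraitDendrogram, k: int) -> dict[int, list[int]]:
    labels = fcluster(dend.linkage_matrix, t=k, criterion="maxclust")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    return clusters


def select_cluster_count(dend: TraitDendrogram, threshold: float = 0.5
                         ) -> TraitClustering:
    """Smallest k for which every cluster's PC1 explains >= threshold.

    Scans k = 1, 2, ...; per cluster the member traits (z-scored) are
    analysed by PCA and the PC1 variance fraction computed; singleton
    clusters count as fraction 1.  If the criterion is only reachable with
    every trait its own cluster, that k is returned with a warning.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must be in (0, 1]")
    n_traits = len(dend.trait_ids)
    for k in range(1, n_traits + 1):
        clusters = _clusters_at(dend, k)
        fractions: dict[int, float] = {}
        for lab, members in clusters.items():
            if len(members) == 1:
                fractions[lab] = 1.0
            else:
                fractions[lab], _ = _pc1_stats(dend.zscores[members, :])
        if all(f >= threshold for f in fractions.values()):
            if k == n_traits and len(clusters) == n_traits:
                logger.warning(
                    "select_cluster_count: criterion only met with all "
                    "%d traits as singletons", n_traits)
            assignment = {dend.trait_ids[i]: lab
                          for lab, members in clusters.items() for i in members}
            return TraitClustering(len(clusters), assignment, fractions)
    raise AssertionError("unreachable: singletons always satisfy the criterion")


def pick_representatives(clustering: TraitClustering,
                         dend: TraitDendrogram) -> TraitClustering:
    """One representative trait per cluster: max |PC1 loading|, ties by id."""
    index = {t: i for i, t in enumerate(dend.trait_ids)}
    reps: dict[int, str] = {}
    by_cluster: dict[int, list[str]] = {}
    for trait, lab in clustering.assignment.items():
        by_cluster.setdefault(lab, []).append(trait)
    for lab, members in by_cluster.items():
        members = sorted(members)
        if len(members) == 1:
            reps[lab] = members[0]
            continue
        rows = [index[t] for t in members]
        _, load = _pc1_stats(dend.zscores[rows, :])
        best = np.max(np.abs(load))
        # lexicographically first among (near-)tied loadings
        reps[lab] = next(t for t, l in zip(members, load)
                         if abs(abs(l) - best) < 1e-12)
    return replace(clustering, representatives=reps)


def reduce_traits(block: OmicsBlock, threshold: float = 0.5,
                  linkage_method: str = "average",
                  distance: str = "abs_correlation") -> TraitClustering:
    """Full pipeline: cluster, select k, pick representatives."""
    dend = cluster_traits(block, linkage_method, distance)
    clustering = select_cluster_count(dend, threshold)
    return pick_representatives(clustering, dend)


def clustering_table(clustering: TraitClustering) -> pd.DataFrame:
    reps = clustering.representatives or {}
    return pd.DataFrame([{
        "trait": t, "cluster": lab,
        "cluster_pc1_fraction": clustering.pc1_fraction[lab],
        "is_representative": reps.get(lab) == t,
    } for t, lab in sorted(clustering.assignment.items())])
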