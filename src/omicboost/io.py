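"""Data containers, delimited-file I/O, and sample alignment.

The canonical in-memory orientation for an omics block is features x
samples: columns are biological samples, rows are molecular features
(genes, wavenumbers, traits).  Phenotype tables in the wild are often
samples-in-rows, so readers accept both orientations via a flag.

Missing values are carried as NaN throughout; accepted missing tokens on
input are the empty string, "NA" and "NaN" (case-insensitive), covering R
and spreadsheet exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("omicboost")

MISSING_TOKENS = frozenset({"", "na", "nan"})

METADATA_ID_COLUMN = "ID"


class ValidationError(ValueError):
    """Input violates a structural contract (duplicate ids, bad shapes...)."""


class ParseError(ValueError):
    """A delimited file contains a cell that cannot be interpreted."""


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in {".tsv", ".tab", ".txt"} else ","


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:5]}")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class OmicsBlock:
    """One feature x sample matrix from a single assay platform.

    Parameters
    ----------
    name
        Block label, e.g. ``"transcriptome"``, ``"ftir"``, ``"phenome"``.
    feature_ids, sample_ids
        Ordered, unique string identifiers for rows and columns.
    values
        Numeric matrix of shape ``(n_features, n_samples)``; NaN marks a
        missing entry.
    feature_axis
        Optional numeric axis with one value per feature, e.g. FTIR
        wavenumbers in cm^-1 (conventionally descending).
    """

    name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    feature_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"block '{self.name}': matrix shape {self.values.shape} does not "
                f"match {len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, f"feature ({self.name})")
        _check_unique(self.sample_ids, f"sample ({self.name})")
        if self.feature_axis is not None:
            self.feature_axis = np.asarray(self.feature_axis, dtype=float)
            if self.feature_axis.shape != (len(self.feature_ids),):
                raise ValidationError(
                    f"block '{self.name}': feature_axis length "
                    f"{self.feature_axis.shape} != feature count {len(self.feature_ids)}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame,
                   feature_axis: np.ndarray | None = None) -> "OmicsBlock":
        return cls(name, list(frame.index.astype(str)),
                   list(frame.columns.astype(str)),
                   frame.to_numpy(dtype=float), feature_axis)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "OmicsBlock":
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name)

    def subset_features(self, mask_or_idx) -> "OmicsBlock":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        axis = None if self.feature_axis is None else self.feature_axis[idx]
        return OmicsBlock(self.name, [self.feature_ids[i] for i in idx],
                          list(self.sample_ids), self.values[idx, :], axis)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise ValidationError(
                f"block '{self.name}' has no sample {exc.args[0]!r}") from exc
        return OmicsBlock(self.name, list(self.feature_ids), list(sample_ids),
                          self.values[:, idx], self.feature_axis)


@dataclass
class SampleMetadata:
    """Sample annotations: an ID per sample plus factor columns.

    ``factors`` is a DataFrame indexed by sample id; each column is one
    experimental factor (condition, time point, replicate, ...), treated as
    nominal unless a consumer declares otherwise.
    """

    factors: pd.DataFrame

    def __post_init__(self) -> None:
        self.factors = self.factors.copy()
        self.factors.index = self.factors.index.astype(str)
        _check_unique(list(self.factors.index), "metadata sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.factors.index)

    def factor(self, name: str) -> pd.Series:
        if name not in self.factors.columns:
            raise ValidationError(
                f"metadata has no factor {name!r}; available: "
                f"{list(self.factors.columns)}")
        return self.factors[name]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.factors.index]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing[:5]}")
        return SampleMetadata(self.factors.loc[list(sample_ids)])


@dataclass
class OutcomeVector:
    """A per-sample outcome: continuous (regression) or binary labels."""

    sample_ids: list[str]
    y: np.ndarray
    task: str = "regression"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y, dtype=float)
        if self.task not in ("regression", "classification"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.y.shape != (len(self.sample_ids),):
            raise ValidationError("outcome length does not match sample_ids")
        if np.isnan(self.y).any():
            raise ValidationError("outcome contains missing values")
        _check_unique(self.sample_ids, "outcome sample")
        if self.task == "classification":
            levels = np.unique(self.y)
            if not np.all(np.isin(levels, (0.0, 1.0))):
                raise ValidationError(
                    f"classification outcome must be 0/1, got levels {levels}")

    def subset(self, sample_ids: Sequence[str]) -> "OutcomeVector":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OutcomeVector(list(sample_ids), self.y[idx], self.task)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_numeric(frame: pd.DataFrame, path: str | Path) -> np.ndarray:
    """String frame -> float matrix honouring the missing-token contract."""
    raw = frame.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = "" if raw[i, j] is None else str(raw[i, j]).strip()
            if cell.lower() in MISSING_TOKENS:
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{frame.index[i]!r}, column {frame.columns[j]!r}"
                ) from None
    return out


def read_block(path: str | Path, name: str,
               orientation: str = "features-in-rows",
               delimiter: str | None = None,
               feature_axis_from_ids: bool = False) -> OmicsBlock:
    """Read a delimited feature matrix into an :class:`OmicsBlock`.

    ``orientation`` is ``"features-in-rows"`` (canonical) or
    ``"samples-in-rows"`` (the file is transposed on read).  With
    ``feature_axis_from_ids`` the feature ids are additionally parsed as a
    numeric axis (wavenumbers).
    """
    if orientation not in ("features-in-rows", "samples-in-rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                        keep_default_na=False)
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    values = _parse_numeric(frame, path)
    if orientation == "samples-in-rows":
        values = values.T
        feature_ids, sample_ids = list(frame.columns), list(frame.index)
    else:
        feature_ids, sample_ids = list(frame.index), list(frame.columns)
    axis = None
    if feature_axis_from_ids:
        try:
            axis = np.array([float(f) for f in feature_ids])
        except ValueError as exc:
            raise ParseError(f"{path}: feature id not numeric: {exc}") from None
    return OmicsBlock(name, feature_ids, sample_ids, values, axis)


def write_block(block: OmicsBlock, path: str | Path,
                delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    block.to_frame().to_csv(path, sep=sep, na_rep="NA")


def read_metadata(path: str | Path, delimiter: str | None = None) -> SampleMetadata:
    """Read a sample-metadata table; must contain an ``ID`` column."""
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if METADATA_ID_COLUMN not in frame.columns:
        raise ValidationError(
            f"{path}: metadata must contain column '{METADATA_ID_COLUMN}'")
    frame = frame.set_index(METADATA_ID_COLUMN)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path,
                   delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    meta.factors.to_csv(path, sep=sep, index_label=METADATA_ID_COLUMN)


def read_outcome(path: str | Path, column: str,
                 task: str = "regression",
                 delimiter: str | None = None) -> OutcomeVector:
    """Read one outcome column from a samples-in-rows table with an ID column."""
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep)
    id_col = METADATA_ID_COLUMN if METADATA_ID_COLUMN in frame.columns \
        else frame.columns[0]
    if column not in frame.columns:
        raise ValidationError(f"{path}: no column {column!r}")
    return OutcomeVector(list(frame[id_col].astype(str)),
                         frame[column].to_numpy(dtype=float), task)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

class Alignment(NamedTuple):
    blocks: list[OmicsBlock]
    metadata: SampleMetadata
    dropped: dict[str, list[str]]


def align_samples(blocks: Sequence[OmicsBlock],
                  metadata: SampleMetadata) -> Alignment:
    """Restrict blocks and metadata to their common samples.

    The shared order is the order of the first block.  Dropped ids are
    reported per input source.
    """
    if not blocks:
        raise ValidationError("align_samples needs at least one block")
    common = set(blocks[0].sample_ids) & set(metadata.sample_ids)
    for b in blocks[1:]:
        common &= set(b.sample_ids)
    if not common:
        counts = {b.name: b.n_samples for b in blocks}
        counts["metadata"] = len(metadata.sample_ids)
        raise ValidationError(
            f"no samples shared by all inputs (per-source counts: {counts})")
    order = [s for s in blocks[0].sample_ids if s in common]
    dropped: dict[str, list[str]] = {}
    for b in blocks:
        gone = [s for s in b.sample_ids if s not in common]
        if gone:
            dropped[b.name] = gone
    meta_gone = [s for s in metadata.sample_ids if s not in common]
    if meta_gone:
        dropped["metadata"] = meta_gone
    for src, gone in dropped.items():
        logger.info("align_samples: dropped %d sample(s) from %s: %s",
                    len(gone), src, gone[:5])
    return Alignment([b.subset_samples(order) for b in blocks],
                     metadata.subset(order), dropped)
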