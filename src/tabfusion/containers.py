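"""Shared in-memory containers for the multi-omic pipeline.

Every stage of the pipeline exchanges :class:`OmicsMatrix` objects — thin
wrappers around a pandas DataFrame whose index holds patient submitter IDs
and whose columns hold feature IDs — tagged with the modality they carry
(``expression``, ``cnv``, ``clinical`` or ``fused``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("expression", "cnv", "clinical", "fused")


@dataclass
class OmicsMatrix:
    """A samples x features block keyed by submitter IDs.

    Parameters
    ----------
    data:
        DataFrame indexed by submitter ID with feature IDs as columns.
    modality:
        One of ``expression``, ``cnv``, ``clinical``, ``fused``.
    categorical:
        Optional tuple of column names that hold integer-encoded categories
        (CNV states, encoded clinical attributes). ``None`` means "all
        continuous" for expression, "all categorical" for cnv.
    """

    data: pd.DataFrame
    modality: str
    categorical: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate submitter IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")

    # -- convenience views ------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(map(str, self.data.columns))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:10]}")
        cat = None
        if self.categorical is not None:
            keep = set(feature_ids)
            cat = tuple(c for c in self.categorical if c in keep)
        return replace(self, data=self.data.loc[:, list(feature_ids)], categorical=cat)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return replace(self, data=self.data.loc[list(sample_ids)])


@dataclass
class CountMatrix:
    """Raw gene-level read counts (samples x genes), non-negative integers."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate gene IDs in count matrix")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative read counts")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list:
        return list(map(str, self.counts.columns))


@dataclass
class GeneAnnotation:
    """Per-gene metadata: exon-union length, biotype, autosome membership.

    ``table`` is indexed by gene ID with columns ``length`` (bp, > 0),
    ``biotype`` (``protein_coding`` or other) and ``autosome`` (bool).
    """

    table: pd.DataFrame

    REQUIRED = ("length", "biotype", "autosome")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col!r}")
        if (self.table["length"] <= 0).any():
            bad = self.table.index[self.table["length"] <= 0].tolist()
            raise ValueError(f"non-positive exon-union length for genes {bad[:5]}")

    def lengths(self, gene_ids: Sequence[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise KeyError(f"genes missing from annotation: {missing[:10]}")
        return self.table.loc[list(gene_ids), "length"].to_numpy(dtype=float)

    def is_protein_coding(self, gene_ids: Sequence[str]) -> np.ndarray:
        return (self.table.loc[list(gene_ids), "biotype"] == "protein_coding").to_numpy()

    def is_autosomal(self, gene_ids: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(gene_ids), "autosome"].to_numpy(dtype=bool)


@dataclass
class SelectionResult:
    """A fitted feature-reduction artifact, transferable to any matrix that
    contains the features it was fitted on."""

    method: str  # ttest | lasso | pca | variance_topk | chi2_topk
    params: dict
    selected_ids: list
    fit_feature_ids: list
    projection: Optional[dict] = None  # pca only: mean, scale, components

    def __post_init__(self) -> None:
        fit = set(self.fit_feature_ids)
        stray = [f for f in self.selected_ids if f not in fit]
        if stray:
            raise ValueError(f"selected features not in fit feature list: {stray[:5]}")


@dataclass
class FusedDataset:
    """Early-fusion result: one matrix whose columns concatenate the
    expression, CNV and clinical blocks for the ID-intersection cohort."""

    matrix: OmicsMatrix
    block_index: list  # [(modality, original_feature_id), ...] one per column
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if len(self.block_index) != self.matrix.n_features:
            raise ValueError("block_index must cover every fused column exactly once")
        if self.labels is not None and not self.labels.index.equals(self.matrix.data.index):
            raise ValueError("labels must be aligned with the fused matrix rows")

    def block_widths(self) -> dict:
        widths: dict = {}
        for modality, _ in self.block_index:
            widths[modality] = widths.get(modality, 0) + 1
        return widths


@dataclass
class CVReport:
    """Per-fold ROC-AUC values with mean +/- sample SD."""

    fold_scores: list
    fold_assignments: np.ndarray
    seed: int
    config_hash: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_scores, ddof=1))

    def summary(self) -> str:
        return f"{self.mean:.3f} +/- {self.sd:.3f} over {len(self.fold_scores)} folds"


@dataclass
class ImportanceVector:
    """Aggregate attention-mask feature importances.

    ``per_sample`` rows are non-negative and sum to one; ``mean`` is the
    dataset-level importance (mean over samples, itself summing to one).
    """

    feature_ids: list
    per_sample: np.ndarray
    mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.per_sample.shape[1] != len(self.feature_ids):
            raise ValueError("importance width must match feature count")
        self.mean = self.per_sample.mean(axis=0)
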