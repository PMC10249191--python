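"""Readers and writers for the pipeline's tab-separated table conventions.

All modality tables are TSV with a header row of feature IDs and the first
column holding patient submitter IDs. Versioned Ensembl gene IDs
(``ENSG...​.N``) are normalized to their unversioned form on read; a
collision after normalization is an error rather than a silent merge.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, OmicsMatrix

__all__ = [
    "normalize_gene_id",
    "read_expression_table",
    "read_counts_table",
    "read_cnv_table",
    "read_clinical_table",
    "read_annotation",
    "write_matrix",
    "write_annotation",
]

_ENSEMBL_VERSION = re.compile(r"^(ENS[A-Z]*G\d{11})\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Strip the version suffix from an Ensembl gene ID, if present."""
    m = _ENSEMBL_VERSION.match(gene_id)
    return m.group(1) if m else gene_id


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.index.name = None
    df.columns = df.columns.map(str)
    return df


def _normalize_columns(df: pd.DataFrame, path) -> pd.DataFrame:
    renamed = [normalize_gene_id(c) for c in df.columns]
    seen: dict = {}
    for orig, new in zip(df.columns, renamed):
        if new in seen:
            raise ValueError(
                f"{path}: gene IDs {seen[new]!r} and {orig!r} collide after version "
                f"normalization ({new})"
            )
        seen[new] = orig
    df.columns = renamed
    return df


def _require_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")


def read_expression_table(path) -> OmicsMatrix:
    """Samples x genes abundance matrix (TPM / FPKM / FPKM-UQ or similar)."""
    df = _normalize_columns(_read_table(path), path)
    _require_numeric(df, path)
    return OmicsMatrix(df.astype(float), modality="expression")


def read_counts_table(path) -> CountMatrix:
    """Samples x genes raw read counts."""
    df = _normalize_columns(_read_table(path), path)
    _require_numeric(df, path)
    vals = df.astype(float)
    if not np.allclose(vals.to_numpy(), np.round(vals.to_numpy())):
        raise ValueError(f"{path}: counts must be integers")
    return CountMatrix(vals.astype(int))


def read_cnv_table(path) -> OmicsMatrix:
    """Samples x genes integer copy-number categories."""
    df = _normalize_columns(_read_table(path), path)
    _require_numeric(df, path)
    vals = df.astype(float)
    if not np.allclose(vals.to_numpy(), np.round(vals.to_numpy())):
        raise ValueError(f"{path}: CNV categories must be integers")
    out = vals.astype(int)
    return OmicsMatrix(out, modality="cnv", categorical=tuple(out.columns))


def read_clinical_table(path, categorical_override=None) -> OmicsMatrix:
    """Clinical attribute table; empty cells are missing values. Column types
    are sniffed (numeric vs categorical) unless overridden."""
    df = _read_table(path)
    categorical = []
    for col in df.columns:
        if categorical_override is not None and col in categorical_override:
            categorical.append(col)
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        if (coerced.isna() & df[col].notna()).any():
            categorical.append(col)
        else:
            df[col] = coerced
    return OmicsMatrix(df, modality="clinical", categorical=tuple(categorical))


def write_matrix(mat: OmicsMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mat.data.to_csv(path, sep="\t", index_label="submitter_id")


def read_annotation(path) -> GeneAnnotation:
    """Gene annotation TSV: gene_id, length, biotype, autosome."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(normalize_gene_id)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene IDs after version normalization")
    df["autosome"] = df["autosome"].astype(bool)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ann.table.to_csv(path, sep="\t", index_label="gene_id")
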