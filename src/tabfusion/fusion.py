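"""CNV/clinical preprocessing and submitter-ID-matched early fusion.

The fusion contract is deliberately strict: rows are the intersection of the
three modalities' submitter IDs (a patient absent from any modality is
dropped everywhere), rows come out in sorted-ID order regardless of input
order, columns are the expression block then the CNV block then the clinical
block, every column is prefixed by its modality so shared gene IDs cannot
collide, and no cell value is altered by fusion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import FusedDataset, OmicsMatrix, SelectionResult
from .selection import apply_selection, chi2_select, variance_top_k

__all__ = [
    "preprocess_clinical",
    "preprocess_cnv",
    "match_and_fuse",
    "missing_clinical_for",
    "MISSING_CODE_LABEL",
]

logger = logging.getLogger(__name__)

MISSING_CODE_LABEL = "__missing__"


def preprocess_clinical(X: OmicsMatrix, max_missing: float = 0.5) -> OmicsMatrix:
    """Drop high-missingness columns, then integer-encode with an explicit
    missing category.

    Columns whose missing fraction is >= ``max_missing`` are dropped.
    Categorical columns are encoded as ``0..K-1`` over their observed levels
    (sorted lexically) with the dedicated missing category as code ``K``.
    Numeric columns keep their values (missing entries imputed with the
    column median) and gain a companion ``<col>__missing`` indicator column.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    df = X.data
    miss_frac = df.isna().mean(axis=0)
    keep = [c for c in df.columns if miss_frac[c] < max_missing]
    if not keep:
        raise ValueError(
            f"all {df.shape[1]} clinical columns exceed the missingness threshold "
            f"{max_missing}; raise max_missing"
        )
    dropped = [c for c in df.columns if c not in keep]
    if dropped:
        logger.info("preprocess_clinical: dropped %d columns over threshold: %s",
                    len(dropped), dropped)
    declared_cat = set(X.categorical or ())
    out = {}
    categorical = []
    for col in keep:
        s = df[col]
        is_cat = col in declared_cat or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)
        if is_cat:
            levels = sorted(map(str, s.dropna().unique()))
            mapping = {lvl: i for i, lvl in enumerate(levels)}
            missing_code = len(levels)
            codes = s.map(lambda v: missing_code if pd.isna(v) else mapping[str(v)])
            out[col] = codes.astype(int)
            categorical.append(col)
        else:
            vals = s.astype(float)
            if vals.isna().any():
                ind = vals.isna().astype(int)
                out[col] = vals.fillna(vals.median())
                out[f"{col}__missing"] = ind
                categorical.append(f"{col}__missing")
            else:
                out[col] = vals
    res = pd.DataFrame(out, index=df.index)
    return OmicsMatrix(res, modality="clinical", categorical=tuple(categorical))


def preprocess_cnv(X: OmicsMatrix, y, top_var: int = 2000, top_chi2: int = 256) -> SelectionResult:
    """Two-stage CNV reduction: keep the ``top_var`` highest-variance genes,
    then the ``top_chi2`` strongest label associations among the survivors
    (contingency chi-squared). Returns the final fitted selection, expressed
    against the full original feature list so it transfers to any matrix."""
    if not top_chi2 <= top_var <= X.n_features:
        raise ValueError(
            f"need top_chi2 <= top_var <= n_features, got {top_chi2}, {top_var}, {X.n_features}"
        )
    stage1 = variance_top_k(X, top_var)
    survivors = apply_selection(stage1, X)
    stage2 = chi2_select(survivors, y, top_chi2)
    return SelectionResult(
        method="chi2_topk",
        params={"top_var": top_var, "top_chi2": top_chi2, **stage2.params},
        selected_ids=stage2.selected_ids,
        fit_feature_ids=X.feature_ids,
    )


def _prefixed(mat: OmicsMatrix, prefix: str) -> pd.DataFrame:
    df = mat.data.copy()
    df.columns = [f"{prefix}:{c}" for c in df.columns]
    return df


def match_and_fuse(expr: OmicsMatrix, cnv: OmicsMatrix, clin: OmicsMatrix,
                   labels=None) -> FusedDataset:
    """Early fusion over the submitter-ID intersection of three modalities.

    Rows: sorted intersection of the three ID sets. Columns: expression,
    then CNV, then clinical, each prefixed with its modality tag. When
    ``labels`` is given it is aligned to the fused rows.
    """
    ids_e, ids_c, ids_l = (set(m.sample_ids) for m in (expr, cnv, clin))
    common = sorted(ids_e & ids_c & ids_l)
    if not common:
        raise ValueError(
            "empty submitter-ID intersection "
            f"(expression={len(ids_e)}, cnv={len(ids_c)}, clinical={len(ids_l)})"
        )
    blocks = []
    block_index = []
    categorical = []
    for mat, tag in ((expr, "expr"), (cnv, "cnv"), (clin, "clin")):
        df = _prefixed(mat.subset_samples(common), tag)
        blocks.append(df)
        block_index.extend((tag, orig) for orig in mat.feature_ids)
        if mat.modality == "cnv":
            categorical.extend(df.columns)
        elif mat.categorical is not None:
            categorical.extend(f"{tag}:{c}" for c in mat.categorical)
    fused = pd.concat(blocks, axis=1)
    if fused.columns.has_duplicates:
        dups = fused.columns[fused.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate fused feature IDs: {dups[:5]}")
    matrix = OmicsMatrix(fused, modality="fused", categorical=tuple(categorical))
    aligned = None
    if labels is not None:
        labels = pd.Series(labels)
        missing = [i for i in common if i not in labels.index]
        if missing:
            raise KeyError(f"labels missing for fused samples: {missing[:10]}")
        aligned = labels.loc[common].astype(int)
    return FusedDataset(matrix=matrix, block_index=block_index, labels=aligned)


def missing_clinical_for(sample_ids, template: OmicsMatrix) -> OmicsMatrix:
    """A clinical block for samples with no clinical records.

    Categorical cells take the template's missing category (its largest
    observed code), missing-indicator columns are set to 1, and numeric
    columns take the template median — the same treatment an all-missing
    patient would get from :func:`preprocess_clinical`.
    """
    df = template.data
    cat = set(template.categorical or ())
    out = {}
    for col in df.columns:
        if col.endswith("__missing"):
            out[col] = np.ones(len(sample_ids), dtype=int)
        elif col in cat:
            out[col] = np.full(len(sample_ids), int(df[col].max()), dtype=int)
        else:
            out[col] = np.full(len(sample_ids), float(df[col].median()))
    res = pd.DataFrame(out, index=list(sample_ids))
    return OmicsMatrix(res, modality="clinical", categorical=template.categorical)
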