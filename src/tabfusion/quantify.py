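"""Gene-level abundance units from raw read counts.

Three units are supported, matching the GDC conventions for gene-level
RNA-Seq quantification:

* **TPM** — length-normalized read rates rescaled per sample so they sum to
  one million.
* **FPKM** — ``C_g * 1e9 / (sum_i C_i * L_g)`` where the denominator sum runs
  over the protein-coding genes of the annotation.
* **FPKM-UQ** — ``C_g * 1e9 / (C_qtl(0.75) * G * L_g)`` where
  ``C_qtl(0.75)`` is the per-sample 75th-percentile protein-coding count and
  ``G`` the number of protein-coding autosomal genes.

FPKM and FPKM-UQ differ only in a per-sample scalar, so their ratio is
constant across genes within a sample, and both are invariant to uniformly
rescaling a sample's counts. Values are returned untransformed; any log
transform is an explicit downstream step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneAnnotation, OmicsMatrix

__all__ = ["compute_tpm", "compute_fpkm", "compute_fpkm_uq", "upper_quartile_counts"]


def _aligned(counts: CountMatrix, ann: GeneAnnotation):
    genes = counts.gene_ids
    lengths = ann.lengths(genes)
    coding = ann.is_protein_coding(genes)
    return np.asarray(counts.counts.to_numpy(), dtype=float), genes, lengths, coding


def compute_tpm(counts: CountMatrix, ann: GeneAnnotation) -> OmicsMatrix:
    """Transcripts per million: each sample's length-normalized rates scaled
    to sum to exactly one million."""
    c, genes, lengths, _ = _aligned(counts, ann)
    rates = c / lengths
    totals = rates.sum(axis=1)
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        names = [counts.sample_ids[i] for i in bad]
        raise ValueError(f"zero total length-normalized count in sample(s) {names}")
    tpm = rates / totals[:, None] * 1e6
    return OmicsMatrix(pd.DataFrame(tpm, index=counts.sample_ids, columns=genes), modality="expression")


def compute_fpkm(counts: CountMatrix, ann: GeneAnnotation) -> OmicsMatrix:
    """Fragments per kilobase per million mapped reads; the per-sample library
    size is the total count over protein-coding genes."""
    c, genes, lengths, coding = _aligned(counts, ann)
    lib = c[:, coding].sum(axis=1)
    bad = np.flatnonzero(lib == 0)
    if bad.size:
        names = [counts.sample_ids[i] for i in bad]
        raise ValueError(f"zero protein-coding library size in sample(s) {names}")
    fpkm = c * 1e9 / (lib[:, None] * lengths[None, :])
    return OmicsMatrix(pd.DataFrame(fpkm, index=counts.sample_ids, columns=genes), modality="expression")


def upper_quartile_counts(counts: CountMatrix, ann: GeneAnnotation) -> np.ndarray:
    """Per-sample 75th-percentile count over protein-coding genes.

    Linear-interpolation quantile over *all* protein-coding counts (zeros
    included); the upstream description names the quantile but not the
    estimator, so the convention is fixed here and documented.
    """
    c, _, _, coding = _aligned(counts, ann)
    if not coding.any():
        raise ValueError("annotation contains no protein-coding genes")
    return np.quantile(c[:, coding], 0.75, axis=1, method="linear")


def compute_fpkm_uq(counts: CountMatrix, ann: GeneAnnotation) -> OmicsMatrix:
    """Upper-quartile FPKM: the library size is replaced by the per-sample
    75th-percentile protein-coding count times the number of protein-coding
    autosomal genes in the annotation."""
    c, genes, lengths, coding = _aligned(counts, ann)
    autosomal = ann.is_autosomal(genes)
    g_count = int((coding & autosomal).sum())
    if g_count == 0:
        raise ValueError("annotation contains no protein-coding autosomal genes")
    uq = upper_quartile_counts(counts, ann)
    bad = np.flatnonzero(uq == 0)
    if bad.size:
        names = [counts.sample_ids[i] for i in bad]
        raise ValueError(f"zero upper-quartile protein-coding count in sample(s) {names}")
    fpkm_uq = c * 1e9 / (uq[:, None] * g_count * lengths[None, :])
    return OmicsMatrix(
        pd.DataFrame(fpkm_uq, index=counts.sample_ids, columns=genes), modality="expression"
    )
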