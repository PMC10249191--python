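"""Synthetic linked multi-omic cohorts with a known planted signal.

Emulates the structure of a colorectal-cancer vital-status study: a labelled
cohort with a ~23% deceased rate, an unlabelled corpus roughly ten times
larger drawn from a related (jittered) distribution, a minority of genes
carrying class signal, per-gene categorical copy-number states, clinical
columns with heavy missingness, and per-modality patient dropout so the
submitter-ID matching step has work to do.

Expression marginals are log-normal (per-gene location and scale), matching
the strong positive skew of upper-quartile-normalized RNA-Seq abundance.
Class signal enters as an additive location shift on the log scale, measured
in units of the per-gene log-scale SD (a standardized effect size). Genes are
conditionally independent given the class label; the two-class mixture is
what induces correlation among informative genes, which is the latent
structure self-supervised pretraining can exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

__all__ = [
    "SyntheticConfig",
    "MultiOmicCohort",
    "generate_labels",
    "generate_expression",
    "generate_cnv",
    "generate_clinical",
    "generate_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the study conditions: 445 labelled patients with
    101 deceased (positive rate ~0.227), an unlabelled corpus ten times the
    labelled size, a few-percent minority of informative genes, five CNV
    categories, and clinical columns whose missingness spans nearly the whole
    unit interval so the retention threshold is always exercised.
    """

    n_labelled: int = 445
    n_unlabelled: int = 4450
    n_genes: int = 2000
    n_informative: int = 60
    effect_size: float = 1.0
    positive_rate: float = 101 / 445
    n_cnv_genes: int = 3000
    n_cnv_states: int = 5
    n_cnv_informative: int = 40
    n_clinical_cols: int = 12
    missing_rate_range: tuple = (0.05, 0.95)
    modality_dropout: float = 0.05
    corpus_jitter: float = 0.25  # per-gene log-location shift SD in the corpus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative must not exceed n_genes")
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must lie in (0, 1)")
        for name in ("n_labelled", "n_unlabelled", "n_genes", "n_cnv_genes", "n_clinical_cols"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cnv_states < 2:
            raise ValueError("n_cnv_states must be at least 2")
        if self.n_cnv_informative > self.n_cnv_genes:
            raise ValueError("n_cnv_informative must not exceed n_cnv_genes")
        lo, hi = self.missing_rate_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("missing_rate_range must be ordered fractions within [0, 1]")
        if not 0 <= self.modality_dropout < 1:
            raise ValueError("modality_dropout must lie in [0, 1)")


@dataclass
class MultiOmicCohort:
    """Linked labelled modalities, an unlabelled corpus, and the ground truth."""

    expression: OmicsMatrix
    cnv: OmicsMatrix
    clinical: OmicsMatrix
    labels: pd.Series  # indexed by the master labelled ID list
    truth: dict
    unlabelled_expression: Optional[OmicsMatrix] = None
    unlabelled_cnv: Optional[OmicsMatrix] = None

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# helpers

def _gene_ids(n: int, prefix: str = "ENSG") -> list:
    return [f"{prefix}{i:011d}" for i in range(n)]


def _patient_ids(n: int, prefix: str = "PT") -> list:
    return [f"{prefix}-{i:06d}" for i in range(n)]


def generate_labels(config: SyntheticConfig) -> pd.Series:
    """Binary vital status (1 = deceased) with the exact configured count of
    positives, shuffled deterministically."""
    rng = np.random.default_rng([config.seed, 0xA])
    n_pos = int(round(config.n_labelled * config.positive_rate))
    n_pos = min(max(n_pos, 1), config.n_labelled - 1)
    y = np.zeros(config.n_labelled, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    return pd.Series(y, index=_patient_ids(config.n_labelled), name="vital_status")


def _gene_params(config: SyntheticConfig):
    rng = np.random.default_rng([config.seed, 0xB])
    mu = rng.normal(2.0, 1.0, size=config.n_genes)
    sigma = rng.uniform(0.4, 1.2, size=config.n_genes)
    informative = np.sort(rng.choice(config.n_genes, size=config.n_informative, replace=False))
    return mu, sigma, informative


def generate_expression(config: SyntheticConfig, labels) -> OmicsMatrix:
    """Labelled expression matrix (n_labelled x n_genes), log-normal values.

    Informative genes have their log-scale location shifted by
    ``effect_size`` per-gene SDs in the positive class; every other gene is
    identically distributed across classes.
    """
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != config.n_labelled:
        raise ValueError("labels length must equal n_labelled")
    mu, sigma, informative = _gene_params(config)
    rng = np.random.default_rng([config.seed, 0xC])
    z = rng.standard_normal((config.n_labelled, config.n_genes))
    log_x = mu + sigma * z
    shift = np.zeros(config.n_genes)
    shift[informative] = config.effect_size * sigma[informative]
    log_x = log_x + np.outer(y, shift)
    genes = _gene_ids(config.n_genes)
    index = labels.index if isinstance(labels, pd.Series) else _patient_ids(config.n_labelled)
    df = pd.DataFrame(np.exp(log_x), index=index, columns=genes)
    return OmicsMatrix(df, modality="expression")


def _unlabelled_expression(config: SyntheticConfig):
    """Corpus drawn from the same two-class mixture with per-gene location
    jitter, mimicking the heterogeneity of a pan-adenoma/adenocarcinoma pool.
    Returns the matrix and the latent class indicator used for the mixture."""
    mu, sigma, informative = _gene_params(config)
    rng = np.random.default_rng([config.seed, 0xD])
    jitter = rng.normal(0.0, config.corpus_jitter, size=config.n_genes) * sigma
    latent = (rng.random(config.n_unlabelled) < config.positive_rate).astype(int)
    z = rng.standard_normal((config.n_unlabelled, config.n_genes))
    shift = np.zeros(config.n_genes)
    shift[informative] = config.effect_size * sigma[informative]
    log_x = mu + jitter + sigma * z + np.outer(latent, shift)
    df = pd.DataFrame(
        np.exp(log_x), index=_patient_ids(config.n_unlabelled, prefix="UL"), columns=_gene_ids(config.n_genes)
    )
    return OmicsMatrix(df, modality="expression"), latent


def _cnv_params(config: SyntheticConfig):
    param_rng = np.random.default_rng([config.seed, 0xF])
    base = param_rng.dirichlet(np.full(config.n_cnv_states, 2.0), size=config.n_cnv_genes)
    informative = np.sort(
        param_rng.choice(config.n_cnv_genes, size=config.n_cnv_informative, replace=False)
    )
    return base, informative


def generate_cnv(config: SyntheticConfig, labels, *, unlabelled: bool = False) -> OmicsMatrix:
    """Per-gene integer copy-number categories in {0..n_cnv_states-1}.

    A subset of ``n_cnv_informative`` genes has a label-conditional category
    distribution (mass tilted toward high states in the positive class); the
    rest are label-independent with gene-specific Dirichlet baselines.
    """
    if config.n_cnv_states < 2:
        raise ValueError("n_cnv_states must be at least 2")
    rng = np.random.default_rng([config.seed, 0xE, int(unlabelled)])
    k = config.n_cnv_states
    base, informative = _cnv_params(config)
    # positive-class distribution: shift mass toward the top category
    tilt = np.linspace(-1.0, 1.0, k)
    pos = base.copy()
    pos[informative] = pos[informative] * np.exp(2.0 * tilt)
    pos[informative] /= pos[informative].sum(axis=1, keepdims=True)

    y = np.asarray(labels, dtype=int)
    n = y.shape[0]
    u = rng.random((n, config.n_cnv_genes))
    cdf_base = np.cumsum(base, axis=1)
    cdf_pos = np.cumsum(pos, axis=1)
    cat_base = (u[:, :, None] > cdf_base[None, :, :]).sum(axis=2)
    cat_pos = (u[:, :, None] > cdf_pos[None, :, :]).sum(axis=2)
    cats = np.where(y[:, None] == 1, cat_pos, cat_base).astype(int)

    genes = _gene_ids(config.n_cnv_genes, prefix="CNVG")
    if unlabelled:
        index = _patient_ids(n, prefix="UL")
    else:
        index = labels.index if isinstance(labels, pd.Series) else _patient_ids(n)
    df = pd.DataFrame(cats, index=index, columns=genes)
    return OmicsMatrix(df, modality="cnv", categorical=tuple(genes))


def generate_clinical(config: SyntheticConfig) -> OmicsMatrix:
    """Clinical attribute table with heavy, column-specific missingness.

    Columns alternate categorical (string categories) and numeric. Per-column
    missing rates are drawn uniformly from ``missing_rate_range``; the last
    column is pinned at the range's upper end so that, whenever the range
    allows it, at least one column exceeds any practical retention threshold.
    Clinical columns carry no class signal by default.
    """
    lo, hi = config.missing_rate_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("missing_rate_range must lie within [0, 1]")
    rng = np.random.default_rng([config.seed, 0x10])
    n, p = config.n_labelled, config.n_clinical_cols
    rates = rng.uniform(lo, hi, size=p)
    rates[-1] = hi
    cols = {}
    for j in range(p):
        name = f"clin_{j:02d}"
        if j % 2 == 0:
            n_cat = int(rng.integers(2, 6))
            vals = pd.Series(
                [f"level_{c}" for c in rng.integers(0, n_cat, size=n)], dtype="object"
            )
        else:
            vals = pd.Series(np.round(rng.normal(60.0, 12.0, size=n), 1))
        mask = rng.random(n) < rates[j]
        vals[mask] = np.nan
        cols[name] = vals
    df = pd.DataFrame(cols)
    df.index = _patient_ids(n)
    categorical = tuple(f"clin_{j:02d}" for j in range(p) if j % 2 == 0)
    return OmicsMatrix(df, modality="clinical", categorical=categorical)


def generate_cohort(config: SyntheticConfig) -> MultiOmicCohort:
    """Full linked cohort: three labelled modalities with per-modality patient
    dropout, an unlabelled expression (and CNV) corpus, and the planted truth."""
    if config.modality_dropout >= 1:
        raise ValueError("modality_dropout must be < 1")
    labels = generate_labels(config)
    expression = generate_expression(config, labels)
    cnv = generate_cnv(config, labels)
    clinical = generate_clinical(config)

    rng = np.random.default_rng([config.seed, 0x11])
    n = config.n_labelled
    n_drop = int(round(config.modality_dropout * n))
    kept = {}
    for name, mat in (("expression", expression), ("cnv", cnv), ("clinical", clinical)):
        drop = rng.choice(n, size=n_drop, replace=False) if n_drop else np.array([], dtype=int)
        keep_mask = np.ones(n, dtype=bool)
        keep_mask[drop] = False
        kept[name] = mat.subset_samples([sid for sid, k in zip(labels.index, keep_mask) if k])

    unlabelled_expr, ul_latent = _unlabelled_expression(config)
    # the unlabelled corpus carries a latent class; CNV shares that latent
    unlabelled_cnv = generate_cnv(config, ul_latent, unlabelled=True)

    _, sigma, informative = _gene_params(config)
    gene_ids = _gene_ids(config.n_genes)
    _, cnv_inf = _cnv_params(config)
    cnv_ids = _gene_ids(config.n_cnv_genes, prefix="CNVG")
    truth = {
        "informative_genes": [gene_ids[i] for i in informative],
        "effects_log_scale": {
            gene_ids[i]: float(config.effect_size * sigma[i]) for i in informative
        },
        "informative_cnv_genes": [cnv_ids[i] for i in cnv_inf],
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
    }
    return MultiOmicCohort(
        expression=kept["expression"],
        cnv=kept["cnv"],
        clinical=kept["clinical"],
        labels=labels,
        truth=truth,
        unlabelled_expression=unlabelled_expr,
        unlabelled_cnv=unlabelled_cnv,
    )
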