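import numpy as np
import pandas as pd
import pytest

from tabfusion import OmicsMatrix, SyntheticConfig, generate_cohort
from tabfusion.containers import CountMatrix, GeneAnnotation


@pytest.fixture(scope="session")
def small_cohort():
    """A compact linked cohort with a clear planted signal, shared by tests
    that only need structure, not statistical power."""
    cfg = SyntheticConfig(
        n_labelled=120, n_unlabelled=400, n_genes=150, n_informative=10,
        effect_size=1.5, n_cnv_genes=200, n_cnv_informative=12,
        n_clinical_cols=8, modality_dropout=0.1, seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def toy_annotation():
    table = pd.DataFrame(
        {
            "length": [1000, 1000, 500, 2000, 800],
            "biotype": ["protein_coding"] * 4 + ["lncRNA"],
            "autosome": [True, True, False, True, True],
        },
        index=[f"G{i}" for i in range(5)],
    )
    return GeneAnnotation(table)


def make_counts(values, sample_ids=None, gene_ids=None) -> CountMatrix:
    values = np.asarray(values)
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[0])]
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(values, index=sample_ids, columns=gene_ids))


def make_matrix(values, modality="expression", sample_ids=None, gene_ids=None,
                categorical=None) -> OmicsMatrix:
    values = np.asarray(values)
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[0])]
    gene_ids = gene_ids or [f"F{i}" for i in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=sample_ids, columns=gene_ids),
                       modality=modality, categorical=categorical)
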