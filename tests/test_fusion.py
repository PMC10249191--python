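"""Clinical/CNV preprocessing and the early-fusion contract."""

import numpy as np
import pandas as pd
import pytest

from tabfusion import match_and_fuse, preprocess_clinical, preprocess_cnv
from tabfusion.containers import OmicsMatrix
from tabfusion.fusion import missing_clinical_for

from conftest import make_matrix


def clinical_fixture(n=20):
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "stage": rng.choice(["i", "ii", "iii"], size=n).astype(object),
        "age": rng.normal(60, 10, size=n),
        "mostly_gone": [np.nan] * (n - 2) + ["x", "y"],
    }, index=[f"P{i}" for i in range(n)])
    return OmicsMatrix(df, modality="clinical", categorical=("stage", "mostly_gone"))


class TestPreprocessClinical:
    def test_high_missingness_column_dropped(self):
        out = preprocess_clinical(clinical_fixture(), max_missing=0.5)
        assert "mostly_gone" not in out.data.columns

    def test_clean_columns_pure_relabeling(self):
        clin = clinical_fixture()
        out = preprocess_clinical(clin, max_missing=0.5)
        # stage has 3 observed levels and no missing entries -> codes 0..2
        assert set(out.data["stage"].unique()) <= {0, 1, 2}
        assert "stage" in out.categorical

    def test_missing_category_encoded_explicitly(self):
        df = pd.DataFrame({"c": ["a", None, "b", "a"]}, index=list("wxyz"))
        clin = OmicsMatrix(df, modality="clinical", categorical=("c",))
        out = preprocess_clinical(clin, max_missing=0.9)
        # levels a=0, b=1, missing=2
        assert out.data["c"].tolist() == [0, 2, 1, 0]

    def test_designed_fixture_leaves_five_columns(self):
        """A fixture designed so exactly 5 clinical features survive the
        missingness threshold."""
        rng = np.random.default_rng(1)
        n = 40
        cols = {}
        for j in range(5):
            cols[f"keep{j}"] = rng.choice(["a", "b"], size=n).astype(object)
        for j in range(3):
            vals = np.array(["a"] * n, dtype=object)
            vals[: int(0.8 * n)] = None
            cols[f"gone{j}"] = vals
        df = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
        clin = OmicsMatrix(df, modality="clinical", categorical=tuple(cols))
        out = preprocess_clinical(clin, max_missing=0.5)
        assert out.n_features == 5

    def test_all_dropped_raises_with_advice(self):
        df = pd.DataFrame({"c": [None, None, "a", None]}, index=list("wxyz"))
        clin = OmicsMatrix(df, modality="clinical", categorical=("c",))
        with pytest.raises(ValueError, match="max_missing"):
            preprocess_clinical(clin, max_missing=0.2)


class TestPreprocessCNV:
    def test_default_style_pipeline_keeps_requested_count(self):
        rng = np.random.default_rng(2)
        X = make_matrix(rng.integers(0, 5, size=(100, 300)), modality="cnv",
                        categorical=tuple(f"F{i}" for i in range(300)))
        y = np.repeat([0, 1], 50)
        sel = preprocess_cnv(X, y, top_var=200, top_chi2=32)
        assert len(sel.selected_ids) == 32

    def test_planted_high_variance_label_gene_survives(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 60)
        vals = rng.integers(0, 2, size=(120, 50))
        vals[:, 7] = y * 4  # high variance and perfectly label-dependent
        X = make_matrix(vals, modality="cnv", categorical=tuple(f"F{i}" for i in range(50)))
        sel = preprocess_cnv(X, y, top_var=20, top_chi2=5)
        assert "F7" in sel.selected_ids
        assert sel.selected_ids[0] == "F7"

    def test_ordering_constraint_enforced(self):
        X = make_matrix(np.zeros((10, 5), dtype=int), modality="cnv")
        with pytest.raises(ValueError):
            preprocess_cnv(X, np.repeat([0, 1], 5), top_var=3, top_chi2=4)


class TestMatchAndFuse:
    def three_way(self):
        e = make_matrix(np.arange(6).reshape(3, 2), sample_ids=["A", "B", "C"],
                        gene_ids=["g1", "g2"])
        c = make_matrix(np.arange(9).reshape(3, 3), modality="cnv",
                        sample_ids=["B", "C", "D"], gene_ids=["g1", "g3", "g4"])
        l = make_matrix(np.array([[1.0]]), modality="clinical",
                        sample_ids=["C"], gene_ids=["age"])
        return e, c, l

    def test_intersection_only_single_row(self):
        e, c, l = self.three_way()
        fused = match_and_fuse(e, c, l)
        assert fused.matrix.sample_ids == ["C"]
        assert fused.matrix.n_features == 2 + 3 + 1

    def test_block_width_accounting(self):
        rng = np.random.default_rng(4)
        ids = [f"P{i}" for i in range(30)]
        e = make_matrix(rng.normal(size=(30, 230)), sample_ids=ids,
                        gene_ids=[f"E{i}" for i in range(230)])
        c = make_matrix(rng.integers(0, 5, size=(30, 256)), modality="cnv",
                        sample_ids=ids, gene_ids=[f"C{i}" for i in range(256)])
        l = make_matrix(rng.normal(size=(30, 5)), modality="clinical",
                        sample_ids=ids, gene_ids=[f"K{i}" for i in range(5)])
        fused = match_and_fuse(e, c, l)
        assert fused.matrix.n_features == 230 + 256 + 5 == 491
        assert fused.block_widths() == {"expr": 230, "cnv": 256, "clin": 5}

    def test_fusion_preserves_values_and_is_row_order_invariant(self):
        rng = np.random.default_rng(5)
        ids = [f"P{i}" for i in range(10)]
        e = make_matrix(rng.normal(size=(10, 4)), sample_ids=ids)
        c = make_matrix(rng.integers(0, 3, size=(10, 3)), modality="cnv", sample_ids=ids)
        l = make_matrix(rng.normal(size=(10, 2)), modality="clinical", sample_ids=ids)
        fused = match_and_fuse(e, c, l)
        # shuffle the input rows: canonical output order must not change
        perm = rng.permutation(10)
        e2 = OmicsMatrix(e.data.iloc[perm], modality="expression")
        fused2 = match_and_fuse(e2, c, l)
        pd.testing.assert_frame_equal(fused.matrix.data, fused2.matrix.data)
        # random probes: fused cells equal source cells
        for _ in range(20):
            i = rng.integers(10)
            j = rng.integers(4)
            sid = fused.matrix.sample_ids[i]
            assert fused.matrix.data.loc[sid, f"expr:{e.feature_ids[j]}"] == \
                e.data.loc[sid, e.feature_ids[j]]

    def test_shared_gene_ids_do_not_collide(self):
        ids = ["A", "B", "C"]
        e = make_matrix(np.eye(3), sample_ids=ids, gene_ids=["g1", "g2", "g3"])
        c = make_matrix(np.eye(3, dtype=int), modality="cnv", sample_ids=ids,
                        gene_ids=["g1", "g2", "g3"])
        l = make_matrix(np.ones((3, 1)), modality="clinical", sample_ids=ids,
                        gene_ids=["g1"])
        fused = match_and_fuse(e, c, l)
        assert fused.matrix.n_features == 7  # prefixing keeps all columns distinct

    def test_empty_intersection_reports_counts(self):
        e = make_matrix(np.eye(2), sample_ids=["A", "B"])
        c = make_matrix(np.eye(2, dtype=int), modality="cnv", sample_ids=["C", "D"])
        l = make_matrix(np.ones((1, 1)), modality="clinical", sample_ids=["E"])
        with pytest.raises(ValueError, match="expression=2"):
            match_and_fuse(e, c, l)

    def test_labels_aligned_to_fused_rows(self):
        e, c, l = self.three_way()
        labels = pd.Series([0, 1, 1, 0], index=["A", "B", "C", "D"])
        fused = match_and_fuse(e, c, l, labels=labels)
        assert fused.labels.tolist() == [1]


def test_missing_clinical_template_fill():
    clin = preprocess_clinical(clinical_fixture(), max_missing=0.9)
    filled = missing_clinical_for(["Q1", "Q2"], clin)
    assert filled.data.columns.tolist() == clin.data.columns.tolist()
    for col in clin.categorical:
        assert (filled.data[col] == clin.data[col].max()).all() or \
            col.endswith("__missing")
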