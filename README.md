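# tabfusion

Self-supervised sequential-attention learning on multi-omic tabular data
for predicting cancer patients' vital status (0 = survived, 1 = deceased).

Bulk RNA-Seq cohorts with outcome labels are small (hundreds of patients)
and wide (tens of thousands of genes), while unlabelled expression data
from related tumour types is plentiful. `tabfusion` implements the full
analysis path for this regime:

1. **Normalization** — TPM, FPKM and FPKM-UQ from raw gene-level counts
   (`FPKM-UQ = C_g·10⁹ / (C_qtl(0.75)·G·L_g)`, with the per-sample
   75th-percentile protein-coding count and the autosomal protein-coding
   gene count G).
2. **Feature reduction** on the labelled cohort — per-gene two-sample
   t-test (p < 0.01), L1-logistic selection, or PCA at 99.9% explained
   variance — transferred unchanged to the unlabelled corpus.
3. **Self-supervised pretraining** of a multi-step attentive tabular
   network: at each decision step a sparsemax attention mask selects a
   sparse instance-wise feature subset (prior-modulated, reuse controlled
   by a relaxation γ); pretraining hides random feature cells and trains
   per-step decoders to reconstruct them under a batch-SD-normalized
   squared loss.
4. **Fine-tuning** on the labelled cohort with early stopping, compared
   against supervised baselines (logistic regression, feedforward net,
   k-NN, gradient-boosted trees, a cyclic additive booster).
5. **Multi-omic early fusion** — CNV (top-2000 variance → top-256
   chi-squared) and clinical blocks (missingness threshold + explicit
   missing category) joined to expression over the submitter-ID
   intersection.
6. **Evaluation and interpretability** — stratified 5-fold
   cross-validated ROC-AUC (mean ± SD) and aggregate attention-mask
   feature importances `M_agg = Σᵢ η[i]·M[i]`, normalized per sample,
   exported as an ordered gene ranking.

The attention network, its sparsemax/capped-simplex projections, the
masked-reconstruction objective and the importance aggregation are
implemented from scratch on a small reverse-mode autodiff engine included
in the package (numpy, float64, CPU); see `docs/methods.md` for the exact
formulations and design choices. A synthetic-cohort generator with a
planted, fully known signal makes every stage testable end to end without
any data download.

## Worked example

```python
import tabfusion as tf

# a linked synthetic cohort: 300 labelled patients (23% deceased),
# a 2000-sample unlabelled corpus, 500 genes of which 20 carry signal
syn = tf.SyntheticConfig(n_labelled=300, n_unlabelled=2000, n_genes=500,
                         n_informative=20, seed=1)
cohort = tf.generate_cohort(syn)

X = cohort.expression
ids = [i for i in X.sample_ids if i in cohort.labels.index]
X = X.subset_samples(ids)
y = cohort.labels.loc[ids].to_numpy()

sel = tf.ttest_select(X, y, alpha=0.01)          # fit on labelled data only
X_sel = tf.apply_selection(sel, X)
corpus = tf.apply_selection(sel, cohort.unlabelled_expression)
print(f"selected {len(sel.selected_ids)} genes")

cfg = tf.SSLConfig(seed=1, max_epochs=60, patience=10)
pretrained = tf.pretrain(corpus, cfg)

from tabfusion.evaluate import tabnet_learner
rep_pre = tf.cross_validate(tabnet_learner(cfg, pretrained), X_sel, y, seed=1)
rep_cold = tf.cross_validate(tabnet_learner(cfg, None), X_sel, y, seed=1)
print("pretrained :", rep_pre.summary())
print("cold start :", rep_cold.summary())
```

Output:

```
selected 25 genes
pretrained : 0.932 +/- 0.039 over 5 folds
cold start : 0.894 +/- 0.085 over 5 folds
```

The t-test recovers all 20 planted genes (plus a handful of false
positives at the raw p < 0.01 cutoff); fine-tuning from the pretrained
weights beats cold-start training because the unlabelled corpus shares
the latent class structure that masked reconstruction learns. Importances
concentrate on the planted genes:

```python
model = tf.finetune(pretrained, X_sel, y)
print(tf.export_importances(tf.explain(model, X_sel), top_k=5))
```

A command-line layer mirrors the library
(`tabfusion simulate|quantify|select|fuse|pretrain|finetune|evaluate|explain|run`),
with full workflows driven by a YAML config via `tabfusion run`.

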