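# Methods

This note documents the models, conventions and numerical choices behind
`tabfusion`, in the order the pipeline runs.

## Problem setting

The package targets binary vital-status prediction (0 = survived,
1 = deceased) for cancer cohorts described by up to three tabular
modalities: gene-level RNA-Seq expression, gene-level copy-number
categories (CNV), and clinical attributes, all keyed by a patient
submitter ID. A much larger unlabelled expression corpus from related
tumour types is available for self-supervised pretraining. The labelled
cohort is imbalanced (roughly 23% positives) and extremely wide relative
to its depth, so the pipeline is: normalize, reduce features on the
labelled data, transfer the reduction to the unlabelled corpus, pretrain,
fine-tune, and evaluate by stratified 5-fold cross-validated ROC-AUC.

## Abundance units

Given raw gene-level counts `C_g` and exon-union lengths `L_g`:

* `TPM_g = (C_g/L_g) / Σ_i (C_i/L_i) · 10^6` — rows sum to exactly one
  million.
* `FPKM_g = C_g · 10^9 / (Σ_i C_i · L_g)` with the library-size sum over
  **protein-coding** genes (the unit is defined relative to the
  protein-coding complement; inflating non-coding counts leaves FPKM
  unchanged).
* `FPKM-UQ_g = C_g · 10^9 / (C_qtl(0.75) · G · L_g)` where `C_qtl(0.75)`
  is the per-sample 75th-percentile protein-coding count and `G` the
  number of protein-coding **autosomal** genes in the annotation.

Conventions fixed here because the unit definitions leave them open: the
upper quartile is the linear-interpolation quantile over *all*
protein-coding counts (zeros included); outputs are stored untransformed
and any log transform is an explicit downstream step. FPKM and FPKM-UQ
differ only by a per-sample scalar, so within a sample their ratio is
constant across genes — a useful invariant the tests exploit.

## Feature reduction

Three labelled-data reducers for expression plus two CNV reducers, all
captured as a transferable `SelectionResult`:

* **t-test** (default): per-gene two-sample test at raw p < 0.01, Welch
  (unequal variance) by default with Student's pooled test as a switch.
  No multiple-testing correction by default — the raw cutoff is the
  convention being reproduced; a BH-FDR switch exists but is off.
  Features constant in both classes are excluded (test undefined).
* **Lasso**: L1 logistic regression at inverse regularisation strength
  0.001 on standardized columns; features with |coef| > 1e-8 survive.
* **PCA**: components retaining 99.9% cumulative explained variance of
  the standardized matrix, applied to new data as a projection using
  fit-time statistics only.
* **CNV**: top-2000 by variance, then top-256 by the Pearson chi-squared
  statistic of the category × label contingency table (no continuity
  correction; single-category features score 0). Note this is the
  contingency-table statistic, not the "observed frequency" chi-squared
  of some library implementations.

Standardization statistics always come from the fitting (labelled) data;
applying a fitted selection to the unlabelled corpus or a held-out fold
therefore leaks nothing.

## Clinical preprocessing and early fusion

Clinical columns with missingness at or above a threshold (default 0.5)
are dropped; surviving categorical columns are integer-encoded with a
dedicated missing category; numeric columns are median-imputed and gain a
binary missing-indicator companion column. Fusion takes the sorted
intersection of the three modalities' submitter IDs (a patient missing
from any modality is dropped everywhere), concatenates
expression | CNV | clinical blocks, and prefixes every column with its
modality so shared Ensembl IDs cannot collide. Fusion never alters a cell
value. Unlabelled patients have no clinical records; their clinical block
is filled with the explicit missing category (the same treatment an
all-missing patient would receive), which is the package's deliberate
interpretation of fusing a clinical-less unlabelled corpus.

## The sequential-attention network

The classifier is a multi-step attentive tabular network built on an
in-package reverse-mode autodiff engine (float64 numpy; no GPU). Per
decision step i:

1. An attentive transformer maps the previous step's attention features
   through a linear layer, multiplies by the prior, and projects onto the
   probability simplex (sparsemax), giving a sparse instance-wise feature
   mask `M[i]` whose rows sum to 1.
2. The prior updates multiplicatively, `prior ← prior · (γ − M[i])`, with
   relaxation γ ≥ 1 controlling feature reuse across steps.
3. Masked features pass through shared + step-specific gated (GLU)
   transformer blocks with √0.5-scaled residuals; the output splits into a
   rectified decision part `d[i]` (accumulated into the prediction head)
   and the next attention part. The step weight is
   `η_b[i] = Σ ReLU(d_b[i])`.

**Capacity cap.** The multiplicative prior alone only prevents feature
reuse when a mask saturates at exactly 1; fractional usage (say 0.6 then
1.0) could exceed a total of γ per feature. To make the γ-bounded-reuse
semantics exact, each step's mask is the projection onto the *capped*
simplex with per-feature cap `min(prior, γ − cumulative_mask, 1)`. The
capped projection coincides with plain sparsemax whenever the caps are
slack — the typical sparse regime — and guarantees that with γ = 1 no
feature's masks ever sum beyond 1. The cap is treated as a constant in
the backward pass.

Categorical fused columns (CNV states, encoded clinical levels) enter
through learned width-1 embeddings (one scalar per category per column);
continuous columns are standardized with statistics from the fitting
data. Input-level normalization is this fixed standardization rather than
(ghost) batch normalization: at the batch sizes used here (≤ 256) a
running input norm converges to the dataset statistics anyway, and the
fixed form keeps training bit-deterministic.

### Self-supervised pretraining

Each batch hides a Bernoulli(`mask_prob`, default 0.2) subset `S` of
feature cells: hidden cells are zeroed in the input and removed from the
initial attention prior (so attention cannot peek), and per-step linear
decoders reconstruct the standardized features from the decision
representations. The loss is

    Σ_b Σ_j | (f̂_bj − f_bj) · S_bj / sqrt(Σ_b (f_bj − mean_b f_j)²) |²

— squared residuals gated by the mask and normalized by each feature's
root sum of squared deviations over the batch (reported per masked cell,
so a structureless dataset plateaus near 1/B). A feature constant within
a batch has no defined normalization: the standalone loss function raises,
while the training loop drops such features from that batch's loss with a
single warning (strictness matters for audit, robustness for training —
e.g. all-missing clinical columns of an unlabelled fused corpus).
Optimization is adaptive-moment (Adam) with a halve-on-plateau learning
rate schedule and early stopping on the epoch loss; the best checkpoint
is returned.

### Fine-tuning and interpretability

Fine-tuning continues from the pretrained weights (or a fresh
initialization for the cold-start comparison) with a binary cross-entropy
head, a stratified validation split monitoring ROC-AUC for early stopping
and plateau-triggered learning-rate decay. Aggregate feature importance
follows the η-weighted mask sum

    M_agg,b,j = Σ_i η_b[i] · M_b,j[i]  /  Σ_j Σ_i η_b[i] · M_b,j[i]

normalized per sample by the *unsquared* denominator so importances form
a distribution (per-sample rows and the dataset mean both sum to 1); the
squared-denominator variant, which breaks the sum-to-1 property, is
available behind `printed_normalization=True` for audit. Samples whose
step weights are all zero fall back to uniform importances with a logged
warning. Dataset-level rankings are exported as an ordered two-column
table usable as input to ordered-gene-list enrichment tools.

### Defaults

n_steps = 3, decision/attention width 8, γ = 1.3, 2 shared + 2
step-specific GLU blocks, batch 256, learning rate 0.02, mask_prob 0.2,
early-stopping patience 15 (pretraining caps at 100 epochs). These are
deliberately small desk-scale defaults; the original setting delegates
them to a hyperparameter search, which `random_search` reproduces as a
seeded random sampler over a declared space (list = categorical, tuple =
uniform or log-uniform) scored by cross-validated ROC-AUC.

## Evaluation

ROC-AUC uses the rank (Mann-Whitney) formulation with half-credit ties;
it is property-tested against exhaustive pair enumeration. Folds are
stratified (the ~23% positive rate is preserved to within one sample per
fold, with exact fold sizes via a continued round-robin over classes);
unstratified folds are a flag. The reported spread is the sample SD over
the five fold scores. Pretraining happens once, outside the CV loop: the
corpus is label-free, so sharing the pretrained weights across folds
leaks no test-fold information, while every fold fine-tunes a fresh copy.

## The synthetic cohort generator

The generator emulates the study conditions so every stage is testable
without downloads: 445 labelled patients at positive rate 101/445, an
unlabelled corpus ten times larger, log-normal expression marginals
(per-gene location ~ N(2,1), log-scale SD ~ U(0.4,1.2)) mimicking the
positive skew of upper-quartile-normalized data, and a minority of
informative genes whose log-location shifts by `effect_size` per-gene SDs
in the deceased class. The unlabelled corpus is drawn from the same
two-class mixture with a latent class at the same rate plus per-gene
location jitter (SD 0.25 of the gene's log-scale SD) standing in for
pan-tumour heterogeneity; the mixture is what induces correlation among
informative genes, i.e. the shared latent structure that masked
reconstruction can learn and fine-tuning can reuse. CNV states follow
per-gene Dirichlet baselines with a high-state tilt in the positive class
for a configurable informative subset; clinical columns alternate
categorical and numeric with per-column missingness drawn from a
configurable range (one column pinned at the range's top so the retention
threshold is always exercised) and carry no class signal by default.
Modality dropout removes an independent fraction of patients from each
modality to exercise submitter-ID matching.

What the generator does **not** emulate — batch effects, sequencing-depth
artifacts, realistic gene-gene correlation networks beyond the class
factor, TCGA barcode semantics — bounds what green tests mean: they
validate the machinery and its statistical calibration, not clinical
performance on real cohorts. ROC-AUC levels attainable on real TCGA
cohorts cannot be reproduced from synthetic data and are not asserted
anywhere; what is asserted is directional: pretraining does not hurt and
typically helps when corpus and cohort share structure, and both arms
clear chance by a wide margin. (At cohort draws where cold-start training
is already near its ceiling, the paired difference can be a small
negative number — the directional claim is about the mean tendency, and
the fixed-seed test cohort exhibits it.)

## Problem sizes

The reference synthetic comparison uses 2000 unlabelled / 300 labelled
samples, 500 genes with 20 informative at effect size 1.0, t-test
selection, and 5 paired seeds — sizes chosen so the full pretrain +
2×5-fold comparison runs in about a minute on one CPU while keeping the
statistical conclusions stable. Calibration checks use 1200-2000 null
genes; recovery checks use effect 1.5 with 150 samples per class, where
two-sample test power at p < 0.01 is essentially 1.

## Known limitations

* The autodiff engine is minimal by design; it supports exactly the ops
  the architecture needs and runs single-threaded float64.
* Width-1 categorical embeddings are the smallest faithful encoding;
  wider embeddings are a natural extension the config does not expose.
* No sparsity (entropy) regularizer on the masks beyond the sparsemax
  mechanism itself.
* `lasso_select` determinism is subject to the solver's internal
  ordering; it is seeded and tested for column-order invariance of the
  selected set, not of coefficients.
* The multimodal synthetic runs fuse a missing-category clinical block
  for unlabelled patients; with signal-free clinical columns the fused
  synthetic problem can score below its unimodal counterpart — the fusion
  machinery, not a performance claim, is what the synthetic multimodal
  path validates.
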