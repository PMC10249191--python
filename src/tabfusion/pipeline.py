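"""End-to-end workflows chaining the pipeline stages.

Three workflows mirror the study designs:

* ``supervised`` — feature reduction on the labelled expression matrix, then
  a cross-validated supervised baseline.
* ``ssl`` — feature reduction on the labelled data, transfer of the same
  selection to the unlabelled corpus, masked-reconstruction pretraining,
  cross-validated fine-tuning, and aggregate-mask importances.
* ``multimodal`` — the ssl workflow on the early fusion of expression, CNV
  and clinical blocks over the submitter-ID intersection.

A run directory receives the echoed configuration, every fitted artifact's
summary, the cross-validation report, the importance ranking, a fusion
manifest where applicable, and a log that records the conventions in force
(t-test variant, upper-quartile estimator, missingness threshold,
importance normalization), so a run is reproducible from its directory
alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fusion as fusion_mod
from . import io as io_mod
from . import quantify as quantify_mod
from . import selection as selection_mod
from . import synthetic as synthetic_mod
from . import tabnet as tabnet_mod
from .baselines import BaselineSpec
from .containers import OmicsMatrix
from .evaluate import baseline_learner, cross_validate, export_importances, tabnet_learner

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    workflow: str = "ssl"  # supervised | ssl | multimodal
    outdir: str = "runs/run"
    seed: int = 0
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    paths: dict = field(default_factory=dict)  # expression/unlabelled_expression/cnv/clinical/labels/annotation/counts
    unit: str = "fpkm_uq"  # tpm | fpkm | fpkm_uq (used when counts are given)
    selection: dict = field(default_factory=lambda: {"method": "ttest", "alpha": 0.01})
    model: dict = field(default_factory=dict)  # family (baseline) or tabnet params
    cv: dict = field(default_factory=lambda: {"k": 5, "stratified": True})
    cnv: dict = field(default_factory=lambda: {"top_var": 2000, "top_chi2": 256})
    clinical: dict = field(default_factory=lambda: {"max_missing": 0.5})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if self.workflow not in ("supervised", "ssl", "multimodal"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if self.unit not in ("tpm", "fpkm", "fpkm_uq"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.simulate:
            for key, p in self.paths.items():
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"configured path {key} does not exist: {p}")


def _load_inputs(cfg: RunConfig):
    """Either simulate a cohort or read the configured tables."""
    if cfg.simulate:
        syn = synthetic_mod.SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
        cohort = synthetic_mod.generate_cohort(syn)
        return cohort
    paths = cfg.paths
    if "counts" in paths and paths.get("annotation"):
        counts = io_mod.read_counts_table(paths["counts"])
        ann = io_mod.read_annotation(paths["annotation"])
        fn = {"tpm": quantify_mod.compute_tpm, "fpkm": quantify_mod.compute_fpkm,
              "fpkm_uq": quantify_mod.compute_fpkm_uq}[cfg.unit]
        expression = fn(counts, ann)
    else:
        expression = io_mod.read_expression_table(paths["expression"])
    labels = pd.read_csv(paths["labels"], sep="\t", index_col=0).iloc[:, 0].astype(int)
    unlabelled = (io_mod.read_expression_table(paths["unlabelled_expression"])
                  if paths.get("unlabelled_expression") else None)
    cnv = io_mod.read_cnv_table(paths["cnv"]) if paths.get("cnv") else None
    clinical = (io_mod.read_clinical_table(paths["clinical"])
                if paths.get("clinical") else None)
    return synthetic_mod.MultiOmicCohort(
        expression=expression, cnv=cnv, clinical=clinical, labels=labels,
        truth={}, unlabelled_expression=unlabelled,
    )


def _fit_selection(cfg: RunConfig, X: OmicsMatrix, y):
    sel_cfg = dict(cfg.selection)
    method = sel_cfg.pop("method", "ttest")
    if method == "ttest":
        return selection_mod.ttest_select(X, y, **sel_cfg)
    if method == "lasso":
        return selection_mod.lasso_select(X, y, **sel_cfg)
    if method == "pca":
        return selection_mod.pca_fit(X, **sel_cfg)
    raise ValueError(f"unknown selection method {method!r}")


def _aligned_labelled(expression: OmicsMatrix, labels: pd.Series):
    ids = [i for i in expression.sample_ids if i in labels.index]
    return expression.subset_samples(ids), labels.loc[ids].to_numpy()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured workflow end-to-end; returns the run directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("tabfusion")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cfg.to_yaml(outdir / "config.yaml")
        logger.info("conventions: t-test=Welch two-sided (raw p cutoff), "
                    "upper-quartile=linear interpolation over all protein-coding counts, "
                    "clinical missingness threshold=%s, importance normalization=unsquared sum",
                    cfg.clinical.get("max_missing", 0.5))
        cohort = _load_inputs(cfg)
        if cfg.workflow == "supervised":
            _run_supervised(cfg, cohort, outdir)
        elif cfg.workflow == "ssl":
            _run_ssl(cfg, cohort, outdir)
        else:
            _run_multimodal(cfg, cohort, outdir)
        return outdir
    except Exception:
        logger.exception("pipeline run failed")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_selection(sel, outdir: Path) -> None:
    payload = {"method": sel.method,
               "params": {k: v for k, v in sel.params.items() if not isinstance(v, dict)},
               "n_selected": len(sel.selected_ids) or sel.params.get("n_components"),
               "selected_ids": sel.selected_ids}
    (outdir / "selection.json").write_text(json.dumps(payload, indent=2))


def _write_report(report, outdir: Path, name: str = "cv_report.json") -> None:
    payload = {"fold_scores": report.fold_scores, "mean": report.mean, "sd": report.sd,
               "seed": report.seed, "config_hash": report.config_hash}
    (outdir / name).write_text(json.dumps(payload, indent=2))
    logger.info("cross-validated ROC-AUC: %s", report.summary())


def _run_supervised(cfg: RunConfig, cohort, outdir: Path) -> None:
    X, y = _aligned_labelled(cohort.expression, cohort.labels)
    sel = _fit_selection(cfg, X, y)
    _write_selection(sel, outdir)
    X_sel = selection_mod.apply_selection(sel, X)
    model_cfg = dict(cfg.model)
    family = model_cfg.pop("family", "logistic")
    spec = BaselineSpec(family, model_cfg, seed=cfg.seed)
    report = cross_validate(baseline_learner(spec), X_sel, y, k=cfg.cv.get("k", 5),
                            seed=cfg.seed, stratified=cfg.cv.get("stratified", True))
    _write_report(report, outdir)


def _make_ssl_config(cfg: RunConfig) -> tabnet_mod.SSLConfig:
    params = {k: v for k, v in cfg.model.items() if k != "family"}
    return tabnet_mod.SSLConfig(**{"seed": cfg.seed, **params})


def _run_ssl(cfg: RunConfig, cohort, outdir: Path) -> None:
    X, y = _aligned_labelled(cohort.expression, cohort.labels)
    sel = _fit_selection(cfg, X, y)
    _write_selection(sel, outdir)
    X_sel = selection_mod.apply_selection(sel, X)
    if cohort.unlabelled_expression is None:
        raise ValueError("ssl workflow needs an unlabelled expression corpus")
    corpus = selection_mod.apply_selection(sel, cohort.unlabelled_expression)
    ssl_cfg = _make_ssl_config(cfg)
    pretrained = tabnet_mod.pretrain(corpus, ssl_cfg)
    pd.DataFrame({"epoch": range(len(pretrained.pretrain_curve)),
                  "loss": pretrained.pretrain_curve}).to_csv(
        outdir / "pretrain_curve.tsv", sep="\t", index=False)
    pretrained.save(outdir / "pretrained_model.npz")
    report = cross_validate(tabnet_learner(ssl_cfg, pretrained), X_sel, y,
                            k=cfg.cv.get("k", 5), seed=cfg.seed,
                            stratified=cfg.cv.get("stratified", True),
                            config_hash=ssl_cfg.hash())
    _write_report(report, outdir)
    final = tabnet_mod.finetune(pretrained, X_sel, y)
    iv = tabnet_mod.explain(final, X_sel)
    export_importances(iv).to_csv(outdir / "importances.tsv", sep="\t", index=False)


def _run_multimodal(cfg: RunConfig, cohort, outdir: Path) -> None:
    if cohort.cnv is None or cohort.clinical is None:
        raise ValueError("multimodal workflow needs cnv and clinical modalities")
    labels = cohort.labels
    # expression block: t-test on the labelled expression
    X_expr, y_expr = _aligned_labelled(cohort.expression, labels)
    expr_sel = _fit_selection(cfg, X_expr, y_expr)
    _write_selection(expr_sel, outdir)
    # cnv block: variance then chi-squared, fitted on labelled CNV
    cnv_lab, y_cnv = _aligned_labelled(cohort.cnv, labels)
    cnv_sel = fusion_mod.preprocess_cnv(cnv_lab, y_cnv, **cfg.cnv)
    # clinical block: threshold + explicit missing category
    clin = fusion_mod.preprocess_clinical(cohort.clinical, **cfg.clinical)

    fused = fusion_mod.match_and_fuse(
        selection_mod.apply_selection(expr_sel, cohort.expression),
        selection_mod.apply_selection(cnv_sel, cohort.cnv),
        clin, labels=labels,
    )
    manifest = {
        "inputs": {"expression": cohort.expression.n_samples, "cnv": cohort.cnv.n_samples,
                   "clinical": cohort.clinical.n_samples},
        "intersection": fused.matrix.n_samples,
        "block_widths": fused.block_widths(),
        "fused_shape": [fused.matrix.n_samples, fused.matrix.n_features],
    }
    ssl_cfg = _make_ssl_config(cfg)
    pretrained = None
    if cohort.unlabelled_expression is not None and cohort.unlabelled_cnv is not None:
        ul_ids = cohort.unlabelled_expression.sample_ids
        ul_fused = fusion_mod.match_and_fuse(
            selection_mod.apply_selection(expr_sel, cohort.unlabelled_expression),
            selection_mod.apply_selection(cnv_sel, cohort.unlabelled_cnv),
            fusion_mod.missing_clinical_for(ul_ids, clin),
        )
        manifest["unlabelled_fused_shape"] = [ul_fused.matrix.n_samples,
                                              ul_fused.matrix.n_features]
        pretrained = tabnet_mod.pretrain(ul_fused.matrix, ssl_cfg)
        pd.DataFrame({"epoch": range(len(pretrained.pretrain_curve)),
                      "loss": pretrained.pretrain_curve}).to_csv(
            outdir / "pretrain_curve.tsv", sep="\t", index=False)
    (outdir / "fusion_manifest.json").write_text(json.dumps(manifest, indent=2))
    y = fused.labels.to_numpy()
    report = cross_validate(tabnet_learner(ssl_cfg, pretrained), fused.matrix, y,
                            k=cfg.cv.get("k", 5), seed=cfg.seed,
                            stratified=cfg.cv.get("stratified", True),
                            config_hash=ssl_cfg.hash())
    _write_report(report, outdir)
    final = tabnet_mod.finetune(pretrained, fused.matrix, y, config=ssl_cfg)
    iv = tabnet_mod.explain(final, fused.matrix)
    export_importances(iv).to_csv(outdir / "importances.tsv", sep="\t", index=False)
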