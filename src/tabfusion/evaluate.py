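"""Cross-validated ROC-AUC reporting, seeded random hyperparameter search,
and importance export.

``roc_auc`` is the rank (Mann-Whitney) formulation: the probability that a
random positive outranks a random negative, ties counting one half. Folds
are stratified by default so the ~23% deceased rate is preserved per fold.
Learners enter :func:`cross_validate` as factories so each fold fits a fresh
model; pretrained weights, being fitted on the label-free corpus only, are
legitimately shared across folds.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .baselines import BaselineSpec, fit_baseline, score
from .containers import CVReport, ImportanceVector, OmicsMatrix

__all__ = [
    "roc_auc",
    "stratified_folds",
    "cross_validate",
    "random_search",
    "SearchResult",
    "export_importances",
    "baseline_learner",
    "tabnet_learner",
]

logger = logging.getLogger(__name__)


def roc_auc(scores, y) -> float:
    """Area under the ROC curve by the rank formulation (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def stratified_folds(y, k: int = 5, seed: int = 0, *, stratified: bool = True) -> np.ndarray:
    """Fold assignment (values 0..k-1) with per-fold class counts within one
    sample of exact proportionality."""
    y = np.asarray(y, dtype=int)
    if stratified and np.bincount(y, minlength=2).min() < k:
        raise ValueError(f"minority class smaller than k={k}; cannot stratify")
    rng = np.random.default_rng([seed, 0x0F])
    folds = np.empty(y.size, dtype=int)
    if stratified:
        # continue the round-robin counter across classes so remainder
        # samples spread over different folds and fold sizes stay exact
        offset = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = (np.arange(idx.size) + offset) % k
            offset += idx.size % k
    else:
        idx = rng.permutation(y.size)
        folds[idx] = np.arange(y.size) % k
    return folds


def baseline_learner(spec: BaselineSpec) -> Callable:
    """Learner factory over :mod:`tabfusion.baselines`."""

    def factory(fold_seed: int):
        fold_spec = BaselineSpec(spec.family, spec.hyperparameters, seed=fold_seed)

        class _L:
            def fit(self, X, y):
                self.model = fit_baseline(fold_spec, X, y)

            def predict_scores(self, X):
                return score(self.model, X)

        return _L()

    return factory


def tabnet_learner(config, pretrained=None) -> Callable:
    """Learner factory for the sequential-attention model; when
    ``pretrained`` is given each fold fine-tunes a fresh copy of it."""
    from dataclasses import replace as _dc_replace

    from .tabnet import finetune, predict_proba

    def factory(fold_seed: int):
        cfg = _dc_replace(config, seed=fold_seed)

        class _L:
            def fit(self, X, y):
                self.model = finetune(pretrained, X, y, config=cfg)

            def predict_scores(self, X):
                return predict_proba(self.model, X)

        return _L()

    return factory


def cross_validate(learner_factory: Callable, X: OmicsMatrix, y, k: int = 5,
                   seed: int = 0, *, stratified: bool = True,
                   config_hash: str = "") -> CVReport:
    """k-fold cross-validated ROC-AUC: a fresh learner per fold, fold scores
    aggregated to mean +/- sample SD."""
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, k=k, seed=seed, stratified=stratified)
    ids = X.sample_ids
    fold_scores = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        learner = learner_factory(int(np.random.default_rng([seed, fold]).integers(2**31)))
        try:
            learner.fit(X.subset_samples([i for i, t in zip(ids, train) if t]), y[train])
            s = learner.predict_scores(X.subset_samples([i for i, t in zip(ids, test) if t]))
        except Exception as exc:
            raise RuntimeError(f"fold {fold} failed: {exc}") from exc
        fold_scores.append(roc_auc(s, y[test]))
    return CVReport(fold_scores=fold_scores, fold_assignments=folds, seed=seed,
                    config_hash=config_hash)


class SearchResult:
    """Trials of a seeded random hyperparameter search with the best by mean
    cross-validated ROC-AUC."""

    def __init__(self, trials: list):
        if not trials:
            raise ValueError("empty search result")
        self.trials = trials
        self.best = max(trials, key=lambda t: t[1].mean)

    @property
    def best_params(self) -> dict:
        return self.best[0]

    @property
    def best_report(self) -> CVReport:
        return self.best[1]


def _sample_space(space: dict, rng) -> dict:
    """One draw from a search space: lists are categorical choices; tuples
    ``(low, high)`` are uniform, ``(low, high, 'log')`` log-uniform."""
    out = {}
    for name, sp in space.items():
        if isinstance(sp, list):
            out[name] = sp[int(rng.integers(len(sp)))]
        elif isinstance(sp, tuple) and len(sp) == 3 and sp[2] == "log":
            out[name] = float(np.exp(rng.uniform(np.log(sp[0]), np.log(sp[1]))))
        elif isinstance(sp, tuple) and len(sp) == 2:
            out[name] = float(rng.uniform(sp[0], sp[1]))
        else:
            raise ValueError(f"cannot interpret search dimension {name!r}: {sp!r}")
    return out


def random_search(space: dict, budget: int, make_factory: Callable, X: OmicsMatrix, y,
                  k: int = 5, seed: int = 0) -> SearchResult:
    """``budget`` independent draws from ``space``; each configured learner
    (``make_factory(params) -> learner factory``) is scored by
    :func:`cross_validate` and the best mean is returned."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng([seed, 0x5EA])
    trials = []
    for t in range(budget):
        params = _sample_space(space, rng)
        report = cross_validate(make_factory(params), X, y, k=k, seed=seed)
        logger.info("trial %d: %s -> %s", t, params, report.summary())
        trials.append((params, report))
    return SearchResult(trials)


def export_importances(iv: ImportanceVector, top_k: Optional[int] = None) -> pd.DataFrame:
    """Ranked two-column table (feature, importance), descending by
    dataset-mean importance with stable original order on ties; suitable as
    an ordered gene list for downstream enrichment tools."""
    n = len(iv.feature_ids)
    if top_k is None:
        top_k = n
    if top_k > n:
        logger.warning("export_importances: top_k=%d clamped to %d features", top_k, n)
        top_k = n
    order = np.argsort(-iv.mean, kind="stable")
    table = pd.DataFrame({
        "feature": [iv.feature_ids[i] for i in order],
        "importance": iv.mean[order],
    })
    return table.head(top_k).reset_index(drop=True)
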