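"""Labelled-data feature reduction and its transfer to unlabelled matrices.

Five selectors share one fitted-artifact type (:class:`SelectionResult`):

* ``ttest_select`` — per-gene two-sample t-test, keep p < alpha (default
  Welch, two-sided; no multiple-testing correction by default, matching the
  raw-cutoff convention of the study design; an optional BH-FDR switch is
  provided but off).
* ``lasso_select`` — L1-penalized logistic regression at a given inverse
  regularisation strength; features with non-zero coefficients survive.
* ``pca_fit`` — principal components retaining a cumulative explained
  variance target (applied as a transform, not a subset).
* ``variance_top_k`` / ``chi2_select`` — the copy-number reducers: highest
  variance, then largest category-vs-label contingency chi-squared.

A fitted selection is applied to any matrix containing the features it was
fitted on (extra features are dropped; missing ones are an error), which is
how the labelled-data selection is transferred to the unlabelled corpus.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .containers import OmicsMatrix, SelectionResult

__all__ = [
    "ttest_select",
    "lasso_select",
    "pca_fit",
    "variance_top_k",
    "chi2_select",
    "apply_selection",
    "contingency_chi2",
]

logger = logging.getLogger(__name__)

LASSO_COEF_TOL = 1e-8


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    return y


def ttest_select(X: OmicsMatrix, y, alpha: float = 0.01, *, equal_var: bool = False,
                 fdr: bool = False) -> SelectionResult:
    """Keep features whose two-sided two-sample t-test p-value is < alpha.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    classical pooled test). Features constant in both groups have no defined
    statistic and are excluded with a logged note.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    y = _check_binary(y)
    vals = X.values.astype(float)
    a, b = vals[y == 1], vals[y == 0]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant features
        _, pvals = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    undefined = ~np.isfinite(pvals)
    if undefined.any():
        logger.info("ttest_select: %d features constant in both groups excluded", undefined.sum())
    pvals = np.where(undefined, 1.0, pvals)
    if fdr:
        pvals = _bh_adjust(pvals)
    keep = pvals < alpha
    ids = [f for f, k in zip(X.feature_ids, keep) if k]
    return SelectionResult(
        method="ttest",
        params={"alpha": alpha, "equal_var": equal_var, "fdr": fdr},
        selected_ids=ids,
        fit_feature_ids=X.feature_ids,
    )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def lasso_select(X: OmicsMatrix, y, inv_reg: float = 0.001, *, max_iter: int = 5000,
                 seed: int = 0) -> SelectionResult:
    """L1-penalized logistic fit; features with |coef| > 1e-8 are selected.

    Columns are standardized with statistics from the fitting (labelled)
    data before the fit. ``inv_reg`` is sklearn's ``C``: smaller means a
    stronger penalty, so ``inv_reg -> 0`` selects nothing.
    """
    if inv_reg <= 0:
        raise ValueError("inv_reg must be positive")
    y = _check_binary(y)
    vals = X.values.astype(float)
    mean = vals.mean(axis=0)
    scale = vals.std(axis=0)
    scale[scale == 0] = 1.0
    z = (vals - mean) / scale
    model = LogisticRegression(
        l1_ratio=1.0, C=inv_reg, solver="liblinear", max_iter=max_iter, random_state=seed,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(z, y)
        except ConvergenceWarning:
            raise RuntimeError(
                f"lasso_select failed to converge within {max_iter} iterations"
            ) from None
    coef = model.coef_.ravel()
    keep = np.abs(coef) > LASSO_COEF_TOL
    ids = [f for f, k in zip(X.feature_ids, keep) if k]
    return SelectionResult(
        method="lasso",
        params={"inv_reg": inv_reg, "max_iter": max_iter, "seed": seed},
        selected_ids=ids,
        fit_feature_ids=X.feature_ids,
    )


def pca_fit(X: OmicsMatrix, variance_target: float = 0.999) -> SelectionResult:
    """Principal components of the standardized matrix retaining the minimal
    leading set whose cumulative explained variance reaches the target."""
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    vals = X.values.astype(float)
    if vals.shape[0] < 2:
        raise ValueError("pca_fit needs at least 2 samples")
    mean = vals.mean(axis=0)
    scale = vals.std(axis=0)
    scale[scale == 0] = 1.0
    z = (vals - mean) / scale
    zc = z - z.mean(axis=0)
    _, s, vt = np.linalg.svd(zc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has zero variance; nothing to project")
    ratio = np.cumsum(var) / total
    rank = int((var > var[0] * 1e-12).sum()) if var.size else 0
    k = int(np.searchsorted(ratio, variance_target - 1e-12) + 1)
    k = min(k, rank if rank else 1)
    return SelectionResult(
        method="pca",
        params={"variance_target": variance_target, "n_components": k,
                "explained_variance_ratio": (var[:k] / total).tolist()},
        selected_ids=[],
        fit_feature_ids=X.feature_ids,
        projection={
            "mean": mean,
            "scale": scale,
            "center": z.mean(axis=0),
            "components": vt[:k],
        },
    )


def variance_top_k(X: OmicsMatrix, k: int) -> SelectionResult:
    """The k features of largest (sample) variance, ties broken by original
    column order."""
    if k > X.n_features:
        raise ValueError(f"k={k} exceeds feature count {X.n_features}")
    if k <= 0:
        raise ValueError("k must be positive")
    var = X.values.astype(float).var(axis=0, ddof=1)
    order = np.argsort(-var, kind="stable")[:k]
    ids = [X.feature_ids[i] for i in order]
    return SelectionResult(
        method="variance_topk",
        params={"k": k},
        selected_ids=ids,
        fit_feature_ids=X.feature_ids,
    )


def contingency_chi2(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson chi-squared statistic of the category x label contingency
    table, without continuity correction. A single-category feature scores 0
    by convention."""
    cats = np.unique(x)
    if cats.size < 2:
        return 0.0
    table = np.zeros((cats.size, 2))
    for i, c in enumerate(cats):
        mask = x == c
        table[i, 0] = np.sum(mask & (y == 0))
        table[i, 1] = np.sum(mask & (y == 1))
    stat, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat)


def chi2_select(X: OmicsMatrix, y, k: int) -> SelectionResult:
    """Top-k features by category-vs-label contingency chi-squared."""
    if k > X.n_features:
        raise ValueError(f"k={k} exceeds feature count {X.n_features}")
    if k <= 0:
        raise ValueError("k must be positive")
    y = _check_binary(y)
    vals = X.values
    if np.issubdtype(vals.dtype, np.floating) and not np.allclose(vals, np.round(vals)):
        raise ValueError("chi2_select expects integer-encoded categorical features")
    vals = vals.astype(int)
    if (vals < 0).any():
        raise ValueError("chi2_select expects non-negative category codes")
    scores = np.array([contingency_chi2(vals[:, j], y) for j in range(vals.shape[1])])
    order = np.argsort(-scores, kind="stable")[:k]
    ids = [X.feature_ids[i] for i in order]
    return SelectionResult(
        method="chi2_topk",
        params={"k": k, "scores": {X.feature_ids[i]: float(scores[i]) for i in order}},
        selected_ids=ids,
        fit_feature_ids=X.feature_ids,
    )


def apply_selection(sel: SelectionResult, X: OmicsMatrix) -> OmicsMatrix:
    """Restrict ``X`` to the fitted selection (or project it, for PCA).

    Extra features in ``X`` are dropped silently; features required by the
    selection but absent from ``X`` raise, listing the missing IDs. The
    statistics baked into a PCA projection come from the fitting data only,
    so applying it to held-out or unlabelled matrices leaks nothing.
    """
    if sel.method == "pca":
        missing = [f for f in sel.fit_feature_ids if f not in X.data.columns]
        if missing:
            raise KeyError(f"matrix lacks features required by the projection: {missing[:10]}")
        proj = sel.projection
        vals = X.data.loc[:, sel.fit_feature_ids].to_numpy(dtype=float)
        z = (vals - proj["mean"]) / proj["scale"] - proj["center"]
        scores = z @ proj["components"].T
        cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
        return OmicsMatrix(
            pd.DataFrame(scores, index=X.sample_ids, columns=cols), modality=X.modality
        )
    missing = [f for f in sel.selected_ids if f not in X.data.columns]
    if missing:
        raise KeyError(f"matrix lacks selected features: {missing[:10]}")
    return X.subset_features(sel.selected_ids)
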