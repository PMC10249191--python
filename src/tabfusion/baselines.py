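"""Supervised comparators behind one uniform fit/score contract.

Five families, with the study's stated hyperparameters as defaults:

* ``logistic`` — L2-penalized logistic regression, inverse regularisation
  strength 0.001 (a deliberately strong penalty).
* ``feedforward`` — MLP with hidden layers (64, 32, 128, 64), ReLU, adaptive
  moments, early stopping on a 20% validation split.
* ``knn`` — 25 nearest neighbours, uniform weighting.
* ``boosted_trees`` — gradient-boosted trees, 120 estimators of depth 3.
* ``cyclic_additive`` — a gradient-boosted additive model: histogram
  boosting constrained to single-feature trees (max 3 leaves, 40 bins, low
  learning rate), so each round fits one feature at a time.

The modelling here is standard supervised learning, so the fits delegate to
established learners; the bespoke part is the uniform contract, the
standardization policy and the seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .containers import OmicsMatrix

__all__ = ["BaselineSpec", "FittedModel", "fit_baseline", "score", "DEFAULT_HYPERPARAMETERS"]

DEFAULT_HYPERPARAMETERS = {
    "logistic": {"inv_reg": 0.001},
    "feedforward": {"hidden_layer_sizes": (64, 32, 128, 64), "max_iter": 400},
    "knn": {"n_neighbors": 25},
    "boosted_trees": {"n_estimators": 120, "max_depth": 3},
    "cyclic_additive": {"max_leaf_nodes": 3, "max_bins": 40, "learning_rate": 0.05,
                        "max_iter": 200},
}

_STANDARDIZED_FAMILIES = {"logistic", "feedforward", "knn"}


@dataclass(frozen=True)
class BaselineSpec:
    family: str
    hyperparameters: dict = _field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(f"unknown baseline family {self.family!r}")
        known = set(DEFAULT_HYPERPARAMETERS[self.family])
        stray = set(self.hyperparameters) - known
        if stray:
            raise ValueError(f"unrecognized hyperparameters for {self.family}: {sorted(stray)}")

    def resolved(self) -> dict:
        return {**DEFAULT_HYPERPARAMETERS[self.family], **self.hyperparameters}


@dataclass
class FittedModel:
    spec: BaselineSpec
    feature_ids: list
    estimator: object
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def _prepare(self, X: OmicsMatrix) -> np.ndarray:
        if X.feature_ids != self.feature_ids:
            if set(X.feature_ids) >= set(self.feature_ids):
                X = X.subset_features(self.feature_ids)
            else:
                missing = sorted(set(self.feature_ids) - set(X.feature_ids))
                raise KeyError(f"matrix lacks fitted features: {missing[:10]}")
        vals = X.values.astype(float)
        if self.mean is not None:
            vals = (vals - self.mean) / self.scale
        return vals


def _build(spec: BaselineSpec):
    hp = spec.resolved()
    if spec.family == "logistic":
        return LogisticRegression(l1_ratio=0.0, C=hp["inv_reg"], max_iter=2000,
                                  random_state=spec.seed)
    if spec.family == "feedforward":
        return MLPClassifier(
            hidden_layer_sizes=hp["hidden_layer_sizes"], activation="relu", solver="adam",
            early_stopping=True, validation_fraction=0.2, max_iter=hp["max_iter"],
            random_state=spec.seed,
        )
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=hp["n_neighbors"], weights="uniform")
    if spec.family == "boosted_trees":
        return XGBClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            eval_metric="logloss", random_state=spec.seed, n_jobs=1, verbosity=0,
        )
    if spec.family == "cyclic_additive":
        return HistGradientBoostingClassifier(
            max_leaf_nodes=hp["max_leaf_nodes"], max_bins=hp["max_bins"],
            learning_rate=hp["learning_rate"], max_iter=hp["max_iter"],
            random_state=spec.seed,
        )
    raise AssertionError(spec.family)


def fit_baseline(spec: BaselineSpec, X: OmicsMatrix, y) -> FittedModel:
    """Fit the requested family; returns a scorer with the fitted schema."""
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("fit_baseline needs both classes present")
    if counts.min() < 2:
        raise ValueError("fit_baseline needs at least 2 samples per class")
    hp = spec.resolved()
    if spec.family == "knn" and hp["n_neighbors"] > X.n_samples:
        raise ValueError(
            f"knn with k={hp['n_neighbors']} exceeds training size {X.n_samples}"
        )
    vals = X.values.astype(float)
    mean = scale = None
    if spec.family in _STANDARDIZED_FAMILIES:
        mean = vals.mean(axis=0)
        scale = vals.std(axis=0)
        scale[scale == 0] = 1.0
        vals = (vals - mean) / scale
    est = _build(spec)
    if spec.family == "cyclic_additive":
        est.set_params(interaction_cst=[{i} for i in range(vals.shape[1])])
    est.fit(vals, y)
    return FittedModel(spec=spec, feature_ids=X.feature_ids, estimator=est,
                       mean=mean, scale=scale)


def score(model: FittedModel, X: OmicsMatrix) -> np.ndarray:
    """Probability-like scores in [0, 1]; higher means more likely deceased."""
    vals = model._prepare(X)
    return model.estimator.predict_proba(vals)[:, 1]
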