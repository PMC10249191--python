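"""Sequential-attention tabular network with self-supervised pretraining.

The encoder runs a fixed number of decision steps. At each step an
*attentive transformer* turns the previous step's attention features into a
sparse instance-wise feature mask via sparsemax, modulated by a *prior* that
records how much each feature has already been used; the relaxation
parameter ``gamma >= 1`` controls reuse (``gamma = 1`` forbids it). The
masked features pass through shared-plus-step-specific gated feature
transformers whose output splits into a rectified decision part (accumulated
into the prediction) and the next step's attention part. The per-step
decision magnitude ``eta_b[i] = sum(ReLU(d_b[i]))`` weighs that step's mask
in the aggregate feature-importance computation.

Self-supervised pretraining masks a Bernoulli subset of each batch's
feature cells, hides them from the encoder (both in the input and in the
initial attention prior) and trains per-step decoders to reconstruct them
under a per-feature, batch-SD-normalized squared loss. Fine-tuning continues
from the pretrained weights with a binary cross-entropy head and early
stopping on a validation ROC-AUC.

Everything runs on the in-package autodiff engine; there is no GPU or
external deep-learning dependency.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np

from .autodiff import Adam, Tensor, sparsemax_np
from .containers import ImportanceVector, OmicsMatrix

__all__ = [
    "SSLConfig",
    "SSLModel",
    "StepMasks",
    "PretrainBatch",
    "sparsemax",
    "attentive_mask",
    "encoder_forward",
    "reconstruction_loss",
    "pretrain",
    "finetune",
    "predict_proba",
    "explain",
    "aggregate_importance",
    "init_model",
]

logger = logging.getLogger(__name__)

_SQRT_HALF = np.sqrt(0.5)


# ---------------------------------------------------------------------------
# configuration and state


@dataclass(frozen=True)
class SSLConfig:
    """Architecture and training hyperparameters.

    ``gamma`` is the attention-prior relaxation (1 forbids feature reuse
    across steps); ``mask_prob`` the Bernoulli cell-masking probability for
    pretraining. Architecture defaults are deliberately small — the
    published setting defers them to a hyperparameter search, exposed here
    through :func:`tabfusion.evaluate.random_search`.
    """

    n_steps: int = 3
    d_decision: int = 8
    d_attention: int = 8
    gamma: float = 1.3
    shared_blocks: int = 2
    step_blocks: int = 2
    mask_prob: float = 0.2
    batch_size: int = 256
    learning_rate: float = 0.02
    weight_decay: float = 0.0
    max_epochs: int = 100
    patience: int = 15
    lr_patience: int = 5
    lr_factor: float = 0.5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if not 0 < self.mask_prob < 1:
            raise ValueError("mask_prob must lie in (0, 1)")

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class StepMasks:
    """Per-step sparse feature masks M[i] (B x D, rows sum to 1) and the
    per-sample step weights eta_b[i] >= 0."""

    masks: list  # n_steps arrays of shape (B, D)
    etas: list  # n_steps arrays of shape (B,)


@dataclass
class PretrainBatch:
    """A masked-reconstruction batch: features ``f``, binary mask ``S``
    (1 = hidden from the encoder, to be reconstructed) and the decoder
    output ``f_hat``."""

    features: np.ndarray
    mask: np.ndarray
    reconstruction: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.mask)
        if not np.isin(s, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")


@dataclass
class SSLModel:
    """Encoder/decoder weights plus the input schema they were fitted to."""

    config: SSLConfig
    feature_ids: list
    mean: np.ndarray
    scale: np.ndarray
    params: dict  # name -> Tensor
    categorical_sizes: dict = field(default_factory=dict)  # col name -> n codes
    pretrain_curve: list = field(default_factory=list)
    finetune_curve: list = field(default_factory=list)
    is_pretrained: bool = False
    is_finetuned: bool = False

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def clone(self) -> "SSLModel":
        new_params = {k: Tensor(p.data.copy(), requires_grad=True) for k, p in self.params.items()}
        return SSLModel(
            config=self.config,
            feature_ids=list(self.feature_ids),
            mean=self.mean.copy(),
            scale=self.scale.copy(),
            params=new_params,
            categorical_sizes=dict(self.categorical_sizes),
            pretrain_curve=list(self.pretrain_curve),
            finetune_curve=list(self.finetune_curve),
            is_pretrained=self.is_pretrained,
            is_finetuned=self.is_finetuned,
        )

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "feature_ids": self.feature_ids,
            "categorical_sizes": self.categorical_sizes,
            "pretrain_curve": self.pretrain_curve,
            "finetune_curve": self.finetune_curve,
            "is_pretrained": self.is_pretrained,
            "is_finetuned": self.is_finetuned,
        }
        arrays = {f"param::{k}": p.data for k, p in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 mean=self.mean, scale=self.scale, **arrays)

    @classmethod
    def load(cls, path) -> "SSLModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            params = {
                k[len("param::"):]: Tensor(npz[k].copy(), requires_grad=True)
                for k in npz.files if k.startswith("param::")
            }
            return cls(
                config=SSLConfig(**meta["config"]),
                feature_ids=meta["feature_ids"],
                mean=npz["mean"].copy(),
                scale=npz["scale"].copy(),
                params=params,
                categorical_sizes=meta["categorical_sizes"],
                pretrain_curve=meta["pretrain_curve"],
                finetune_curve=meta["finetune_curve"],
                is_pretrained=meta["is_pretrained"],
                is_finetuned=meta["is_finetuned"],
            )


# ---------------------------------------------------------------------------
# core primitives


def sparsemax(z) -> np.ndarray:
    """Euclidean projection of ``z`` (vector or row-batch) onto the
    probability simplex; sparse counterpart of softmax."""
    return sparsemax_np(z)


def attentive_mask(a, prior, weight, bias, gamma: float, cap=None):
    """One attentive-transformer application.

    ``M = sparsemax(prior * (a @ weight + bias))`` projected so that no
    entry exceeds its remaining capacity ``cap`` (default
    ``min(prior, 1)``); the updated prior is ``prior * (gamma - M)``. The
    capacity cap makes the no-reuse semantics of ``gamma = 1`` exact — a
    feature can never accumulate more than ``gamma`` total mask mass — while
    coinciding with plain sparsemax whenever the caps are slack (the typical
    sparse-mask regime). Accepts numpy arrays or engine tensors; returns
    tensors (use ``.data`` for the arrays).
    """
    a = Tensor.as_tensor(a)
    prior = Tensor.as_tensor(prior)
    weight = Tensor.as_tensor(weight)
    bias = Tensor.as_tensor(bias)
    if a.data.shape[1] != weight.data.shape[0] or prior.data.shape[1] != weight.data.shape[1]:
        raise ValueError(
            f"shape mismatch: attention {a.data.shape}, weight {weight.data.shape}, "
            f"prior {prior.data.shape}"
        )
    if cap is None:
        cap = np.minimum(prior.data, 1.0)
    z = a @ weight + bias
    mask = (prior * z).capped_sparsemax_rows(cap)
    new_prior = prior * (Tensor(float(gamma)) - mask)
    return mask, new_prior


def reconstruction_loss(batch: PretrainBatch) -> float:
    """Masked-reconstruction loss: sum over samples b and features j of
    ``|(f_hat - f) * S / sqrt(sum_b (f - mean_b f)^2)|^2``.

    The denominator is the root sum of squared deviations of feature j over
    the batch; a feature that is masked anywhere but constant over the batch
    makes the loss undefined and raises.
    """
    f = np.asarray(batch.features, dtype=float)
    fhat = np.asarray(batch.reconstruction, dtype=float)
    s = np.asarray(batch.mask, dtype=float)
    dev = f - f.mean(axis=0, keepdims=True)
    denom = np.sqrt((dev**2).sum(axis=0))
    zero = (denom == 0) & (s.sum(axis=0) > 0)
    if zero.any():
        raise ZeroDivisionError(
            f"zero batch SD for masked feature index(es) {np.flatnonzero(zero).tolist()}"
        )
    safe = np.where(denom == 0, 1.0, denom)
    resid = (fhat - f) * s / safe
    return float((resid**2).sum())


# ---------------------------------------------------------------------------
# model construction and forward pass


def _glorot(rng, shape):
    fan_in = shape[0]
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def init_model(X: OmicsMatrix, config: SSLConfig) -> SSLModel:
    """A freshly initialized model whose input schema (feature order,
    standardization statistics, categorical code books) is taken from ``X``."""
    rng = np.random.default_rng([config.seed, 0x7AB])
    vals = X.values.astype(float)
    d = vals.shape[1]
    cat_cols = list(X.categorical or ())
    cat_sizes = {}
    for c in cat_cols:
        cat_sizes[c] = int(X.data[c].max()) + 1
    mean = vals.mean(axis=0)
    scale = vals.std(axis=0)
    scale[scale == 0] = 1.0

    h = config.d_decision + config.d_attention
    params = {}
    for b in range(config.shared_blocks):
        d_in = d if b == 0 else h
        params[f"shared{b}_Wv"] = Tensor(_glorot(rng, (d_in, h)), requires_grad=True)
        params[f"shared{b}_bv"] = Tensor(np.zeros(h), requires_grad=True)
        params[f"shared{b}_Wg"] = Tensor(_glorot(rng, (d_in, h)), requires_grad=True)
        params[f"shared{b}_bg"] = Tensor(np.zeros(h), requires_grad=True)
    for step in range(config.n_steps + 1):  # step 0 builds the initial attention
        for b in range(config.step_blocks):
            params[f"step{step}_{b}_Wv"] = Tensor(_glorot(rng, (h, h)), requires_grad=True)
            params[f"step{step}_{b}_bv"] = Tensor(np.zeros(h), requires_grad=True)
            params[f"step{step}_{b}_Wg"] = Tensor(_glorot(rng, (h, h)), requires_grad=True)
            params[f"step{step}_{b}_bg"] = Tensor(np.zeros(h), requires_grad=True)
    for step in range(1, config.n_steps + 1):
        params[f"att{step}_W"] = Tensor(_glorot(rng, (config.d_attention, d)), requires_grad=True)
        params[f"att{step}_b"] = Tensor(np.zeros(d), requires_grad=True)
        params[f"dec{step}_W"] = Tensor(_glorot(rng, (config.d_decision, d)), requires_grad=True)
        params[f"dec{step}_b"] = Tensor(np.zeros(d), requires_grad=True)
    params["head_W"] = Tensor(np.zeros((config.d_decision, 1)), requires_grad=True)
    params["head_b"] = Tensor(np.zeros(1), requires_grad=True)
    if cat_cols:
        total = sum(cat_sizes.values())
        params["emb"] = Tensor(rng.normal(0.0, 0.1, size=total), requires_grad=True)

    return SSLModel(
        config=config, feature_ids=X.feature_ids, mean=mean, scale=scale, params=params,
        categorical_sizes=cat_sizes,
    )


def _standardized(model: SSLModel, X: OmicsMatrix) -> np.ndarray:
    """Numeric representation: every column (categorical codes included)
    standardized by the fit-time statistics. This is the reconstruction
    target during pretraining."""
    if X.feature_ids != model.feature_ids:
        if set(X.feature_ids) >= set(model.feature_ids):
            X = X.subset_features(model.feature_ids)
        else:
            missing = sorted(set(model.feature_ids) - set(X.feature_ids))
            raise KeyError(f"matrix lacks model features: {missing[:10]}")
    return (X.values.astype(float) - model.mean) / model.scale


def _input_tensor(model: SSLModel, X: OmicsMatrix) -> Tensor:
    """Model input: standardized continuous columns, learned width-1
    embeddings for categorical columns, restored to original column order."""
    if X.feature_ids != model.feature_ids:
        X = X.subset_features(model.feature_ids)
    if not model.categorical_sizes:
        return Tensor(_standardized(model, X))
    cat_cols = [c for c in model.feature_ids if c in model.categorical_sizes]
    cont_cols = [c for c in model.feature_ids if c not in model.categorical_sizes]
    pos = {c: i for i, c in enumerate(model.feature_ids)}
    cont_idx = np.array([pos[c] for c in cont_cols], dtype=int)
    std = _standardized(model, X)
    parts = []
    if cont_cols:
        parts.append(Tensor(std[:, cont_idx]))
    offsets = {}
    off = 0
    for c, size in model.categorical_sizes.items():
        offsets[c] = off
        off += size
    codes = np.column_stack([
        np.clip(X.data[c].to_numpy().astype(int), 0, model.categorical_sizes[c] - 1)
        + offsets[c]
        for c in cat_cols
    ])
    parts.append(model.params["emb"].embed_lookup(codes))
    stacked = Tensor.concat_cols(parts)
    order = np.argsort(np.array([pos[c] for c in cont_cols + cat_cols]))
    return stacked.permute_cols(order)


def _glu_block(x: Tensor, params: dict, prefix: str) -> Tensor:
    v = x @ params[f"{prefix}_Wv"] + params[f"{prefix}_bv"]
    g = x @ params[f"{prefix}_Wg"] + params[f"{prefix}_bg"]
    out = v * g.sigmoid()
    if out.data.shape == x.data.shape:
        out = (out + x) * _SQRT_HALF
    return out


def _feature_transform(x: Tensor, model: SSLModel, step: int) -> Tensor:
    cfg = model.config
    h = x
    for b in range(cfg.shared_blocks):
        h = _glu_block(h, model.params, f"shared{b}")
    for b in range(cfg.step_blocks):
        h = _glu_block(h, model.params, f"step{step}_{b}")
    return h


def _encode(model: SSLModel, x: Tensor, prior0: Optional[np.ndarray] = None):
    """Run the multi-step encoder. Returns (d_agg, masks, etas, step_ds)."""
    cfg = model.config
    dd = cfg.d_decision
    h_width = cfg.d_decision + cfg.d_attention
    h0 = _feature_transform(x, model, step=0)
    a = h0.slice_cols(dd, h_width)
    prior = Tensor(np.ones_like(x.data) if prior0 is None else np.asarray(prior0, dtype=float))
    cum = np.zeros_like(x.data) if prior0 is None else 1.0 - np.asarray(prior0, dtype=float)
    d_agg = None
    masks, etas, step_ds = [], [], []
    for step in range(1, cfg.n_steps + 1):
        cap = np.clip(np.minimum(prior.data, cfg.gamma - cum), 0.0, 1.0)
        mask, prior = attentive_mask(
            a, prior, model.params[f"att{step}_W"], model.params[f"att{step}_b"], cfg.gamma,
            cap=cap,
        )
        cum = cum + mask.data
        xm = x * mask
        hidden = _feature_transform(xm, model, step=step)
        if not np.isfinite(hidden.data).all():
            raise FloatingPointError(f"non-finite activations at decision step {step}")
        d = hidden.slice_cols(0, dd).relu()
        a = hidden.slice_cols(dd, h_width)
        d_agg = d if d_agg is None else d_agg + d
        masks.append(mask)
        etas.append(d.sum(axis=1))
        step_ds.append(d)
    return d_agg, masks, etas, step_ds


def encoder_forward(X: OmicsMatrix, model: SSLModel):
    """Public forward pass: returns (decision_output, StepMasks, embedding)
    as numpy arrays, where ``embedding`` is the accumulated rectified
    decision representation."""
    x = _input_tensor(model, X)
    d_agg, masks, etas, _ = _encode(model, x)
    decision = (d_agg @ model.params["head_W"] + model.params["head_b"]).data.ravel()
    sm = StepMasks(masks=[m.data for m in masks], etas=[e.data for e in etas])
    return decision, sm, d_agg.data


# ---------------------------------------------------------------------------
# interpretability


def aggregate_importance(masks: StepMasks, feature_ids, *, printed_normalization: bool = False) -> ImportanceVector:
    """Aggregate attention-mask importances.

    Per sample: ``M_agg_bj = sum_i eta_b[i] M_bj[i]`` normalized over
    features so each row sums to one. The ``printed_normalization`` variant
    divides instead by ``sum_j sum_i eta_b[i] M_bj[i]^2`` (the squared-mask
    form), which does not yield a distribution; it is kept for audit only.
    Samples with all-zero step weights fall back to uniform importances with
    a logged warning.
    """
    m = np.stack(masks.masks)  # (steps, B, D)
    e = np.stack(masks.etas)  # (steps, B)
    if m.shape[:2] != e.shape:
        raise ValueError("masks and etas are shape-inconsistent")
    num = np.einsum("ib,ibj->bj", e, m)
    if printed_normalization:
        denom = np.einsum("ib,ibj->b", e, m**2)
    else:
        denom = num.sum(axis=1)
    dead = denom <= 0
    if dead.any():
        logger.warning("aggregate_importance: %d sample(s) with zero step weights; "
                       "falling back to uniform importances", int(dead.sum()))
    d_feat = m.shape[2]
    per_sample = np.where(
        dead[:, None], np.full((m.shape[1], d_feat), 1.0 / d_feat),
        num / np.where(dead, 1.0, denom)[:, None],
    )
    return ImportanceVector(feature_ids=list(feature_ids), per_sample=per_sample)


def explain(model: SSLModel, X: OmicsMatrix, *, printed_normalization: bool = False) -> ImportanceVector:
    """Aggregate feature importances of ``model`` over the samples of ``X``."""
    _, sm, _ = encoder_forward(X, model)
    return aggregate_importance(sm, model.feature_ids, printed_normalization=printed_normalization)


# ---------------------------------------------------------------------------
# training loops


class _Plateau:
    """Halve the learning rate when the monitored metric stalls."""

    def __init__(self, optimizer: Adam, patience: int, factor: float, mode: str = "min"):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.sign = 1.0 if mode == "min" else -1.0
        self.best = np.inf
        self.stale = 0

    def step(self, value: float) -> None:
        v = self.sign * value
        if v < self.best - 1e-12:
            self.best = v
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.opt.lr *= self.factor
                self.stale = 0


def _batches(n: int, batch_size: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def pretrain(corpus: OmicsMatrix, config: SSLConfig) -> SSLModel:
    """Masked-reconstruction pretraining on an unlabelled corpus.

    Each batch hides a Bernoulli(``mask_prob``) subset of cells from the
    encoder (zeroed in the input and removed from the initial attention
    prior) and the per-step decoders learn to reconstruct them; the loss is
    the batch-SD-normalized squared residual over masked cells, reported per
    masked cell. Training stops early when the epoch loss has not improved
    for ``patience`` epochs; the best checkpoint is returned.
    """
    model = init_model(corpus, config)
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0x51])
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    sched = _Plateau(opt, cfg.lr_patience, cfg.lr_factor, mode="min")
    target = _standardized(model, corpus)
    n = target.shape[0]
    best = np.inf
    best_params = None
    stale = 0
    warned_const = False
    curve = []
    for epoch in range(cfg.max_epochs):
        total, count = 0.0, 0
        for idx in _batches(n, cfg.batch_size, rng):
            f = target[idx]
            s = (rng.random(f.shape) < cfg.mask_prob).astype(float)
            if s.sum() == 0:
                continue
            dev = f - f.mean(axis=0, keepdims=True)
            denom = np.sqrt((dev**2).sum(axis=0))
            const = (denom == 0) & (s.sum(axis=0) > 0)
            if const.any():
                if not warned_const:
                    warnings.warn(
                        f"{int(const.sum())} feature(s) constant within a batch; "
                        "dropping them from the reconstruction loss",
                        RuntimeWarning, stacklevel=2,
                    )
                    warned_const = True
                s = np.where(const[None, :], 0.0, s)
                if s.sum() == 0:
                    continue
            denom = np.where(denom == 0, 1.0, denom)
            x_in = _input_tensor(model, corpus.subset_samples([corpus.sample_ids[i] for i in idx]))
            x_masked = x_in * (1.0 - s)
            _, _, _, step_ds = _encode(model, x_masked, prior0=(1.0 - s))
            fhat = None
            for step, d in enumerate(step_ds, start=1):
                part = d @ model.params[f"dec{step}_W"] + model.params[f"dec{step}_b"]
                fhat = part if fhat is None else fhat + part
            resid = (fhat - Tensor(f)) * Tensor(s / denom)
            loss = resid.square().sum() * (1.0 / s.sum())
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * s.sum()
            count += s.sum()
        epoch_loss = total / max(count, 1)
        curve.append(epoch_loss)
        sched.step(epoch_loss)
        if epoch_loss < best - 1e-9:
            best = epoch_loss
            best_params = {k: p.data.copy() for k, p in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_params is None:
        warnings.warn("pretraining loss never decreased; returning initial weights",
                      RuntimeWarning, stacklevel=2)
    else:
        for k, p in model.params.items():
            p.data = best_params[k]
    model.pretrain_curve = curve
    model.is_pretrained = True
    return model


def _stratified_holdout(y: np.ndarray, fraction: float, rng):
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    rng.shuffle(idx_pos)
    rng.shuffle(idx_neg)
    n_vp = max(int(round(fraction * idx_pos.size)), 1)
    n_vn = max(int(round(fraction * idx_neg.size)), 1)
    val = np.concatenate([idx_pos[:n_vp], idx_neg[:n_vn]])
    train = np.concatenate([idx_pos[n_vp:], idx_neg[n_vn:]])
    return np.sort(train), np.sort(val)


def finetune(model: Optional[SSLModel], X: OmicsMatrix, y, config: Optional[SSLConfig] = None) -> SSLModel:
    """Supervised fine-tuning (or cold-start training when ``model`` is
    ``None``) of the classifier on binary vital status.

    A stratified validation split monitors ROC-AUC for early stopping and
    learning-rate decay; the best-validation checkpoint is returned. The
    original model is left untouched.
    """
    from .evaluate import roc_auc  # local import to avoid a cycle

    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("finetune requires both classes present in y")
    if model is None:
        if config is None:
            raise ValueError("need a config when training from scratch")
        model = init_model(X, config)
    else:
        model = model.clone()
        if config is not None:
            model = replace_config(model, config)
    cfg = model.config
    rng = np.random.default_rng([cfg.seed, 0x52])
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    sched = _Plateau(opt, cfg.lr_patience, cfg.lr_factor, mode="max")
    ids = X.sample_ids
    tr, va = _stratified_holdout(y, cfg.val_fraction, rng)
    x_val = X.subset_samples([ids[i] for i in va])
    best_auc, best_params, stale = -np.inf, None, 0
    curve = []
    for epoch in range(cfg.max_epochs):
        for idx in _batches(tr.size, cfg.batch_size, rng):
            batch = tr[idx]
            x_in = _input_tensor(model, X.subset_samples([ids[i] for i in batch]))
            d_agg, _, _, _ = _encode(model, x_in)
            logits = d_agg @ model.params["head_W"] + model.params["head_b"]
            loss = logits.bce_with_logits(y[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_scores = predict_proba(model, x_val)
        auc = roc_auc(val_scores, y[va]) if np.unique(y[va]).size == 2 else 0.5
        curve.append(auc)
        sched.step(auc)
        if auc > best_auc + 1e-9:
            best_auc, stale = auc, 0
            best_params = {k: p.data.copy() for k, p in model.params.items()}
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    model.finetune_curve = curve
    model.is_finetuned = True
    return model


def replace_config(model: SSLModel, config: SSLConfig) -> SSLModel:
    """Swap training hyperparameters while keeping architecture and weights
    (architecture fields must match)."""
    for f_name in ("n_steps", "d_decision", "d_attention", "shared_blocks", "step_blocks"):
        if getattr(model.config, f_name) != getattr(config, f_name):
            raise ValueError(f"cannot change architecture field {f_name!r} of a trained model")
    model.config = config
    return model


def predict_proba(model: SSLModel, X: OmicsMatrix) -> np.ndarray:
    """Probability that each sample is class 1 (deceased)."""
    x = _input_tensor(model, X)
    d_agg, _, _, _ = _encode(model, x)
    logits = (d_agg @ model.params["head_W"] + model.params["head_b"]).data.ravel()
    return 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
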