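"""The sequential-attention model: mask algebra, the reconstruction loss
against a naive oracle, importance aggregation, and training behaviour."""

import numpy as np
import pandas as pd
import pytest

from tabfusion import (
    OmicsMatrix,
    PretrainBatch,
    SSLConfig,
    StepMasks,
    aggregate_importance,
    attentive_mask,
    encoder_forward,
    finetune,
    predict_proba,
    pretrain,
    reconstruction_loss,
)
from tabfusion.tabnet import SSLModel, init_model

from conftest import make_matrix


def naive_reconstruction_loss(f, fhat, s):
    """Three-loop evaluation of the masked, batch-SD-normalized squared
    reconstruction residual."""
    b_n, d_n = f.shape
    total = 0.0
    for j in range(d_n):
        mean = sum(f[b, j] for b in range(b_n)) / b_n
        denom = np.sqrt(sum((f[b, j] - mean) ** 2 for b in range(b_n)))
        for b in range(b_n):
            if s[b, j]:
                total += ((fhat[b, j] - f[b, j]) / denom) ** 2
    return total


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        f = np.array([[0.0], [2.0]])
        assert reconstruction_loss(PretrainBatch(f, np.ones_like(f), f.copy())) == 0.0

    def test_empty_mask_is_zero(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(4, 3))
        fhat = rng.normal(size=(4, 3))
        assert reconstruction_loss(PretrainBatch(f, np.zeros_like(f), fhat)) == 0.0

    def test_hand_example(self):
        # B=2, D=1, f=(0,2), fhat=(1,1): denom = sqrt(2), loss = 1/2 + 1/2 = 1
        f = np.array([[0.0], [2.0]])
        fhat = np.array([[1.0], [1.0]])
        loss = reconstruction_loss(PretrainBatch(f, np.ones_like(f), fhat))
        assert loss == pytest.approx(1.0, rel=1e-12)

    def test_matches_naive_three_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            b_n = int(rng.integers(2, 8))
            d_n = int(rng.integers(1, 6))
            f = rng.normal(size=(b_n, d_n))
            fhat = rng.normal(size=(b_n, d_n))
            s = (rng.random((b_n, d_n)) < 0.5).astype(float)
            got = reconstruction_loss(PretrainBatch(f, s, fhat))
            want = naive_reconstruction_loss(f, fhat, s)
            assert got == pytest.approx(want, rel=1e-6)

    def test_constant_masked_feature_errors(self):
        f = np.ones((3, 2))
        s = np.zeros((3, 2))
        s[0, 1] = 1
        with pytest.raises(ZeroDivisionError, match="1"):
            reconstruction_loss(PretrainBatch(f, s, f + 1))


class TestAttentiveMask:
    def test_rows_sum_to_one_and_identical_inputs_give_identical_masks(self):
        rng = np.random.default_rng(2)
        a = np.tile(rng.normal(size=(1, 4)), (5, 1))
        prior = np.ones((5, 6))
        w = rng.normal(size=(4, 6))
        mask, _ = attentive_mask(a, prior, w, np.zeros(6), gamma=1.3)
        np.testing.assert_allclose(mask.data.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(mask.data, np.tile(mask.data[:1], (5, 1)))

    def test_gamma_one_forbids_reuse(self):
        # a mask entry of 1 zeroes the prior for that feature
        a = np.array([[5.0]])
        prior = np.ones((1, 3))
        w = np.array([[10.0, 0.0, 0.0]])
        mask, new_prior = attentive_mask(a, prior, w, np.zeros(3), gamma=1.0)
        assert mask.data[0, 0] == pytest.approx(1.0)
        assert new_prior.data[0, 0] == pytest.approx(0.0)

    def test_two_step_hand_trace_with_gamma_two(self):
        # step 1: z = (2, 1), prior ones -> sparsemax((2, 1)) = (1, 0)
        #   new prior = (1*(2-1), 1*(2-0)) = (1, 2)
        # step 2: z = (3, 2) -> prior*z = (3, 4); sorted (4, 3): k=1 since
        #   1 + 2*3 = 7 is not > 7 -> tau = 3 -> mask = (0, 1)
        #   new prior = (1*(2-0), 2*(2-1)) = (2, 2)
        prior = np.ones((1, 2))
        m1, p1 = attentive_mask(np.array([[1.0]]), prior, np.array([[2.0, 1.0]]),
                                np.zeros(2), gamma=2.0)
        np.testing.assert_allclose(m1.data, [[1.0, 0.0]])
        np.testing.assert_allclose(p1.data, [[1.0, 2.0]])
        m2, p2 = attentive_mask(np.array([[1.0]]), p1.data, np.array([[3.0, 2.0]]),
                                np.zeros(2), gamma=2.0)
        np.testing.assert_allclose(m2.data, [[0.0, 1.0]])
        np.testing.assert_allclose(p2.data, [[2.0, 2.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            attentive_mask(np.ones((2, 3)), np.ones((2, 5)), np.ones((3, 4)),
                           np.zeros(4), gamma=1.3)


class TestEncoder:
    def cfg(self, **kw):
        base = dict(n_steps=3, d_decision=4, d_attention=4, shared_blocks=1,
                    step_blocks=1, seed=5)
        base.update(kw)
        return SSLConfig(**base)

    def test_mask_rows_sum_to_one_on_random_input(self):
        rng = np.random.default_rng(3)
        X = make_matrix(rng.normal(size=(20, 10)))
        model = init_model(X, self.cfg())
        _, sm, _ = encoder_forward(X, model)
        for m in sm.masks:
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-10)
            assert (m >= 0).all()

    def test_gamma_one_cumulative_mask_bounded_by_one(self):
        rng = np.random.default_rng(4)
        X = make_matrix(rng.normal(size=(30, 8)))
        model = init_model(X, self.cfg(gamma=1.0))
        _, sm, _ = encoder_forward(X, model)
        cumulative = np.sum(sm.masks, axis=0)
        assert (cumulative <= 1.0 + 1e-9).all()

    def test_zero_head_gives_zero_decision_output(self):
        rng = np.random.default_rng(5)
        X = make_matrix(rng.normal(size=(6, 5)))
        model = init_model(X, self.cfg())  # head is zero-initialized
        decision, _, _ = encoder_forward(X, model)
        np.testing.assert_allclose(decision, 0.0)

    def test_etas_nonnegative(self):
        rng = np.random.default_rng(6)
        X = make_matrix(rng.normal(size=(12, 7)))
        model = init_model(X, self.cfg())
        _, sm, _ = encoder_forward(X, model)
        for e in sm.etas:
            assert (e >= 0).all()


class TestAggregateImportance:
    def test_uniform_masks_give_uniform_importance(self):
        masks = [np.full((3, 4), 0.25)] * 2
        etas = [np.ones(3), np.ones(3)]
        iv = aggregate_importance(StepMasks(masks, etas), [f"f{i}" for i in range(4)])
        np.testing.assert_allclose(iv.per_sample, 0.25)

    def test_single_step_importance_is_the_mask(self):
        rng = np.random.default_rng(7)
        m = np.abs(rng.normal(size=(5, 3)))
        m /= m.sum(axis=1, keepdims=True)
        iv = aggregate_importance(StepMasks([m], [np.ones(5)]), ["a", "b", "c"])
        np.testing.assert_allclose(iv.per_sample, m)

    def test_two_step_hand_computation(self):
        m1 = np.array([[1.0, 0.0, 0.0]])
        m2 = np.array([[0.0, 0.5, 0.5]])
        etas = [np.array([2.0]), np.array([1.0])]
        iv = aggregate_importance(StepMasks([m1, m2], etas), ["a", "b", "c"])
        # weighted sum = (2, 0.5, 0.5); normalized by 3
        np.testing.assert_allclose(iv.per_sample, [[2 / 3, 1 / 6, 1 / 6]])

    def test_per_sample_and_dataset_importances_sum_to_one(self):
        rng = np.random.default_rng(8)
        X = make_matrix(rng.normal(size=(15, 9)))
        model = init_model(X, SSLConfig(n_steps=2, d_decision=3, d_attention=3,
                                        shared_blocks=1, step_blocks=1, seed=1))
        # nonzero head so etas vary
        from tabfusion.tabnet import explain
        iv = explain(model, X)
        np.testing.assert_allclose(iv.per_sample.sum(axis=1), 1.0, atol=1e-9)
        assert iv.mean.sum() == pytest.approx(1.0)

    def test_zero_eta_sample_falls_back_to_uniform(self):
        masks = [np.array([[0.7, 0.3]])]
        etas = [np.array([0.0])]
        iv = aggregate_importance(StepMasks(masks, etas), ["a", "b"])
        np.testing.assert_allclose(iv.per_sample, [[0.5, 0.5]])


def correlated_corpus(n=2000, d=50, seed=0):
    """Features sharing a strong one-factor structure: reconstruction from
    the unmasked features is genuinely possible."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    load = rng.uniform(0.8, 1.2, size=d)
    X = np.outer(latent, load) + 0.3 * rng.standard_normal((n, d))
    return make_matrix(X)


class TestPretrain:
    def test_loss_halves_on_correlated_features(self):
        corpus = correlated_corpus()
        cfg = SSLConfig(n_steps=2, d_decision=8, d_attention=8, shared_blocks=1,
                        step_blocks=1, max_epochs=30, patience=8, seed=3)
        model = pretrain(corpus, cfg)
        curve = model.pretrain_curve
        assert min(curve) < curve[0] / 2

    def test_pure_noise_plateaus_near_unexplainable_level(self):
        """With independent features the best reconstruction is the feature
        mean, leaving the full normalized residual: per masked cell the loss
        cannot drop far below 1/B (the batch-normalized variance share)."""
        rng = np.random.default_rng(9)
        corpus = make_matrix(rng.standard_normal((600, 30)))
        cfg = SSLConfig(n_steps=2, d_decision=4, d_attention=4, shared_blocks=1,
                        step_blocks=1, max_epochs=20, patience=6, batch_size=200,
                        seed=4)
        model = pretrain(corpus, cfg)
        floor = 1.0 / 200  # = 1/B with the per-masked-cell reporting convention
        assert 0.5 * floor < min(model.pretrain_curve) < 3 * floor

    def test_same_seed_identical_weights(self):
        corpus = correlated_corpus(n=300, d=20, seed=5)
        cfg = SSLConfig(n_steps=2, d_decision=4, d_attention=4, shared_blocks=1,
                        step_blocks=1, max_epochs=5, patience=5, seed=6)
        m1 = pretrain(corpus, cfg)
        m2 = pretrain(corpus, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)


class TestFinetune:
    def test_separable_toy_reaches_perfect_validation_auc(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 60)
        X = make_matrix(np.column_stack([y * 4.0 + rng.normal(scale=0.1, size=120),
                                         rng.normal(size=120)]))
        cfg = SSLConfig(n_steps=2, d_decision=4, d_attention=4, shared_blocks=1,
                        step_blocks=1, max_epochs=60, patience=15, seed=7)
        model = finetune(None, X, y, config=cfg)
        assert max(model.finetune_curve) == pytest.approx(1.0)

    def test_label_permutation_gives_chance_auc_on_held_out_data(self):
        rng = np.random.default_rng(11)
        X_train = make_matrix(rng.standard_normal((150, 10)))
        X_test = make_matrix(rng.standard_normal((150, 10)),
                             sample_ids=[f"T{i}" for i in range(150)])
        y_train = rng.permutation(np.repeat([0, 1], 75))
        y_test = rng.permutation(np.repeat([0, 1], 75))
        cfg = SSLConfig(n_steps=2, d_decision=4, d_attention=4, shared_blocks=1,
                        step_blocks=1, max_epochs=20, patience=6, seed=8)
        model = finetune(None, X_train, y_train, config=cfg)
        from tabfusion import roc_auc
        auc = roc_auc(predict_proba(model, X_test), y_test)
        assert abs(auc - 0.5) < 0.15  # ~3 SD of the null AUC at this size

    def test_single_class_rejected(self):
        X = make_matrix(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            finetune(None, X, np.zeros(10, dtype=int),
                     config=SSLConfig(seed=0))


def test_model_roundtrips_through_serialization(tmp_path):
    rng = np.random.default_rng(12)
    X = make_matrix(rng.normal(size=(20, 6)))
    cfg = SSLConfig(n_steps=2, d_decision=3, d_attention=3, shared_blocks=1,
                    step_blocks=1, seed=9)
    model = init_model(X, cfg)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = SSLModel.load(path)
    assert loaded.config == cfg
    assert loaded.feature_ids == model.feature_ids
    for k in model.params:
        np.testing.assert_array_equal(loaded.params[k].data, model.params[k].data)
    X2 = make_matrix(rng.normal(size=(5, 6)))
    np.testing.assert_allclose(predict_proba(model, X2), predict_proba(loaded, X2))
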