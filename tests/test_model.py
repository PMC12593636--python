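"""Dual-view classifier: pooling, fusion, weighting, augmentation, training."""

import numpy as np
import pytest

from lobescore.model import (
    DualViewLobeClassifier,
    TinyBackbone,
    TrainConfig,
    _to_channels,
    augment,
    class_weights,
    fuse_and_classify,
    pool_slices,
    slice_features,
    weighted_loss,
)
from lobescore.nn import Linear
from lobescore.preprocess import LobeSample


class _DoublingBackbone:
    """Test backbone with a closed-form slice map: feature = 2 * channel sum."""

    feature_channels = 1

    def forward(self, x):
        return (2 * x.sum(axis=1, keepdims=True))


def _sample(rng, s_c=4, s_a=3, side=16, label=1, patient="P0", exam="P0_E0"):
    return LobeSample(
        coronal_stack=rng.random((s_c, side, side)),
        axial_stack=rng.random((s_a, side, side)),
        lobe_id=1, pathology="mucus", patient_id=patient, exam_id=exam, label=label,
    )


class TestSliceFeatures:
    def test_constant_slice_analytic_mean(self):
        stack = np.full((2, 8, 8), 0.25)
        desc = slice_features(stack, _DoublingBackbone())
        # channel-repeated input: 3 channels of 0.25, doubled sum = 1.5
        assert np.allclose(desc, 1.5)

    def test_duplicated_slice_duplicates_descriptor(self):
        rng = np.random.default_rng(0)
        stack = rng.random((2, 8, 8))
        dup = np.concatenate([stack, stack[:1]])
        desc = slice_features(dup, _DoublingBackbone())
        assert np.allclose(desc[0], desc[2])

    def test_single_slice_shape(self):
        bb = TinyBackbone((4, 4, 8), np.random.default_rng(0))
        desc = slice_features(np.random.default_rng(1).random((1, 16, 16)), bb)
        assert desc.shape == (1, 8)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            slice_features(np.empty((0, 8, 8)), _DoublingBackbone())


class TestPoolSlices:
    def test_elementwise_max(self):
        assert np.array_equal(pool_slices(np.array([[1, 5], [3, 2]])), [3, 5])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.random((6, 8))
        assert np.array_equal(pool_slices(d), pool_slices(d[::-1]))

    def test_dominated_descriptor_changes_nothing(self):
        d = np.array([[2.0, 3.0], [1.0, 4.0]])
        extended = np.vstack([d, [[1.5, 2.5]]])
        assert np.array_equal(pool_slices(d), pool_slices(extended))


class TestFuseAndClassify:
    def test_zero_head_uniform_probabilities(self):
        head = Linear(4, 3, np.random.default_rng(0))
        head.W[...] = 0
        head.b[...] = 0
        _, probs = fuse_and_classify(np.ones(2), np.ones(2), head)
        assert np.allclose(probs, 1 / 3)

    def test_toy_head_hand_checked_logits(self):
        head = Linear(4, 3, np.random.default_rng(0))
        head.W[...] = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 1]], float)
        head.b[...] = np.array([0.5, 0, -1], float)
        logits, _ = fuse_and_classify(np.array([2.0, 3.0]), np.array([4.0, 5.0]), head)
        assert np.allclose(logits, [2.5, 3.0, 8.0])

    def test_view_order_matters(self):
        rng = np.random.default_rng(2)
        head = Linear(4, 3, rng)
        a, b = rng.random(2), rng.random(2)
        l1, _ = fuse_and_classify(a, b, head)
        l2, _ = fuse_and_classify(b, a, head)
        assert not np.allclose(l1, l2)

    def test_dimension_mismatch(self):
        head = Linear(4, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            fuse_and_classify(np.ones(3), np.ones(3), head)


class TestClassWeights:
    def test_balanced_counts_unit_weights(self):
        assert np.allclose(class_weights([10, 10, 10]), 1.0)

    def test_reference_cohort_ordering(self):
        # bronchiectasis totals: score 1 dominates, score 2 rarest
        w = class_weights([563, 2825, 374])
        assert w[1] < w[0] < w[2]

    def test_scale_invariance(self):
        assert np.allclose(class_weights([5, 8, 2]), class_weights([10, 16, 4]))

    def test_inverted_direction(self):
        w = class_weights([563, 2825, 374], invert=True)
        assert w[2] < w[0] < w[1]

    def test_zero_count_gets_max(self):
        w = class_weights([10, 0, 5])
        assert w[1] == max(w)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            class_weights([0, 0, 0])


class TestWeightedLoss:
    def test_unit_weights_is_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=3)
        loss, _ = weighted_loss(logits, 1, np.ones(3))
        p = np.exp(logits) / np.exp(logits).sum()
        assert loss == pytest.approx(-np.log(p[1]), abs=1e-7)

    def test_confident_correct_loss_vanishes(self):
        loss, _ = weighted_loss(np.array([100.0, 0.0, 0.0]), 0, np.ones(3))
        assert loss < 1e-8

    def test_linear_in_weight(self):
        logits = np.array([0.3, -0.2, 0.1])
        l1, _ = weighted_loss(logits, 2, np.array([1.0, 1.0, 1.0]))
        l2, _ = weighted_loss(logits, 2, np.array([1.0, 1.0, 2.0]))
        assert l2 == pytest.approx(2 * l1)

    def test_gradient_matches_numerics(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=3)
        w = np.array([0.5, 1.5, 1.0])
        _, grad = weighted_loss(logits, 0, w)
        eps = 1e-6
        for i in range(3):
            d = np.zeros(3)
            d[i] = eps
            lp, _ = weighted_loss(logits + d, 0, w)
            lm, _ = weighted_loss(logits - d, 0, w)
            assert grad[i] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)


class TestAugment:
    def test_double_flip_is_identity(self):
        rng = np.random.default_rng(0)
        stack = rng.random((3, 8, 8))
        assert np.array_equal(stack[:, :, ::-1][:, :, ::-1], stack)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        stack_c = rng.random((2, 16, 16))
        stack_a = rng.random((3, 16, 16))
        c1, a1 = augment(stack_c, stack_a, np.random.default_rng(11))
        c2, a2 = augment(stack_c, stack_a, np.random.default_rng(11))
        assert np.array_equal(c1, c2) and np.array_equal(a1, a2)

    def test_shapes_and_range_preserved(self):
        rng = np.random.default_rng(1)
        c, a = augment(rng.random((2, 16, 16)), rng.random((4, 16, 16)),
                       np.random.default_rng(0))
        assert c.shape == (2, 16, 16) and a.shape == (4, 16, 16)
        assert c.min() >= 0 and c.max() <= 1

    def test_rotation_applied_consistently_across_slices(self):
        base = np.zeros((2, 16, 16))
        base[:, 4, 4] = 1.0  # same marker in both slices
        c, _ = augment(base, base.copy(), np.random.default_rng(2))
        assert np.allclose(c[0], c[1])


class TestTrainConfig:
    def test_step_schedule_matches_protocol(self):
        cfg = TrainConfig()
        assert cfg.lr_at_epoch(0) == pytest.approx(1e-5)
        assert cfg.lr_at_epoch(14) == pytest.approx(1e-5)
        # 16th epoch: first epoch after the step at 15
        assert cfg.lr_at_epoch(15) == pytest.approx(1e-5 * 0.4)
        assert cfg.lr_at_epoch(30) == pytest.approx(1e-5 * 0.4**2)

    def test_invalid_patience(self):
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=200, max_epochs=100)


class TestClassifier:
    @pytest.fixture(scope="class")
    def toy_data(self):
        """Linearly separable toy task: bright stacks vs dark stacks."""
        rng = np.random.default_rng(0)
        train, val = [], []
        for i in range(24):
            label = i % 3
            brightness = [0.1, 0.5, 0.9][label]
            s = LobeSample(
                coronal_stack=np.clip(rng.normal(brightness, 0.05, (3, 16, 16)), 0, 1),
                axial_stack=np.clip(rng.normal(brightness, 0.05, (2, 16, 16)), 0, 1),
                lobe_id=1, pathology="mucus",
                patient_id=f"T{i}" if i < 18 else f"V{i}",
                exam_id=f"E{i}", label=label,
            )
            (train if i < 18 else val).append(s)
        return train, val

    @pytest.fixture(scope="class")
    def fitted(self, toy_data):
        train, val = toy_data
        clf = DualViewLobeClassifier(
            backbone_channels=(4, 8, 8), lr=0.05, momentum=0.0, max_epochs=12,
            early_stop_patience=11, augment=False, seed=0,
        )
        return clf.fit(train, X_val=val)

    def test_training_loss_decreases(self, fitted):
        losses = fitted.history_["train_loss"].to_numpy()
        assert losses[-1] < losses[0]

    def test_predictions_deterministic(self, fitted, toy_data):
        _, val = toy_data
        p1 = fitted.predict_proba(val)
        p2 = fitted.predict_proba(val)
        assert np.array_equal(p1, p2)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_slice_order_invariance(self, fitted, toy_data):
        _, val = toy_data
        s = val[0]
        shuffled = LobeSample(
            coronal_stack=s.coronal_stack[::-1].copy(),
            axial_stack=s.axial_stack[::-1].copy(),
            lobe_id=s.lobe_id, pathology=s.pathology,
            patient_id=s.patient_id, exam_id=s.exam_id, label=s.label,
        )
        p1 = fitted.predict_proba([s])
        p2 = fitted.predict_proba([shuffled])
        assert np.allclose(p1, p2, atol=1e-10)

    def test_learns_separable_task(self, fitted, toy_data):
        _, val = toy_data
        acc = (fitted.predict(val) == [s.label for s in val]).mean()
        assert acc >= 0.8

    def test_early_stop_with_frozen_weights(self, toy_data):
        train, val = toy_data
        clf = DualViewLobeClassifier(
            backbone_channels=(4, 4, 4), lr=1e-30, max_epochs=10,
            early_stop_patience=1, augment=False, seed=0,
        )
        clf.fit(train, X_val=val)
        # epoch 0 improves over inf; epoch 1 cannot improve -> stop after 2
        assert len(clf.history_) == 2

    def test_requires_validation_set(self, toy_data):
        train, _ = toy_data
        clf = DualViewLobeClassifier(max_epochs=2, early_stop_patience=1)
        with pytest.raises(ValueError, match="validation"):
            clf.fit(train)

    def test_rejects_patient_leakage(self, toy_data):
        train, _ = toy_data
        clf = DualViewLobeClassifier(max_epochs=2, early_stop_patience=1)
        with pytest.raises(ValueError, match="leak|both"):
            clf.fit(train, X_val=train[:3])

    def test_sklearn_params_roundtrip(self):
        clf = DualViewLobeClassifier(lr=0.01, seed=3)
        params = clf.get_params()
        assert params["lr"] == 0.01
        clone = DualViewLobeClassifier(**params)
        assert clone.get_params() == params
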