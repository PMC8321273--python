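"""Class weights, label fusion, and classifier training behaviour."""

import numpy as np
import pytest

from toolmotion.classifier import (
    NEGATIVE_CLASS,
    POSITIVE_CLASS,
    ClassifierConfig,
    PerFrameBaseline,
    SequenceToolClassifier,
    compute_class_weights,
    sequence_label,
    weighted_ce,
)


class TestClassWeights:
    def test_imbalanced_sequence_counts(self):
        # the 756:2894 scissors/needle-holders imbalance
        w = compute_class_weights({"scissors": 756, "needle_holders": 2894})
        assert w["scissors"] == pytest.approx(3650 / 1512, abs=1e-12)
        assert w["needle_holders"] == pytest.approx(3650 / 5788, abs=1e-12)
        assert w["scissors"] == pytest.approx(2.4140, abs=1e-4)
        assert w["needle_holders"] == pytest.approx(0.6306, abs=1e-4)

    def test_equal_counts_unit_weights(self):
        w = compute_class_weights({"a": 10, "b": 10})
        assert w == {"a": 1.0, "b": 1.0}

    def test_small_counts(self):
        w = compute_class_weights({"a": 1, "b": 3})
        assert w["a"] == pytest.approx(2.0)
        assert w["b"] == pytest.approx(2 / 3)

    def test_count_weighted_mean_is_one(self):
        counts = {"a": 7, "b": 19, "c": 4}
        w = compute_class_weights(counts)
        total = sum(counts.values())
        assert sum(w[c] * n for c, n in counts.items()) / total == pytest.approx(1.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights({"a": 0, "b": 5})


class TestSequenceLabel:
    def test_mean_fusion(self):
        p_final, label = sequence_label(np.full(5, 0.9))
        assert p_final == pytest.approx(0.9)
        assert label == POSITIVE_CLASS

    def test_boundary_half_is_positive(self):
        p_final, label = sequence_label(np.array([0.2, 0.8]))
        assert p_final == 0.5 and label == POSITIVE_CLASS

    def test_below_half_is_negative(self):
        _, label = sequence_label(np.array([0.2, 0.3]))
        assert label == NEGATIVE_CLASS

    def test_mean_matches_arithmetic_oracle(self, rng):
        p = rng.uniform(size=37)
        p_final, _ = sequence_label(p, "mean")
        assert p_final == pytest.approx(float(np.sum(p)) / len(p), abs=1e-12)

    def test_last_and_max_fusion(self):
        p = np.array([0.1, 0.9, 0.4])
        assert sequence_label(p, "last")[0] == pytest.approx(0.4)
        assert sequence_label(p, "max")[0] == pytest.approx(0.9)

    def test_empty_or_unknown_fusion(self):
        with pytest.raises(ValueError):
            sequence_label(np.array([]))
        with pytest.raises(ValueError):
            sequence_label(np.array([0.5]), "median")


def test_weighted_ce_wrapper_matches_closed_form():
    loss = weighted_ce(np.array([0.5, 0.5]), 1, (1.0, 1.0))
    assert loss == pytest.approx(np.log(2), abs=1e-12)
    with pytest.raises(ValueError):
        weighted_ce(np.array([0.5]), 2)


def make_separable_features(n_per_class, T=10, d=128, seed=0):
    """Two Gaussian motion signatures: class differs in temporal oscillation."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    t = np.arange(T)
    for label, freq in ((POSITIVE_CLASS, 0.5), (NEGATIVE_CLASS, 0.1)):
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            base = np.sin(2 * np.pi * freq * t + phase)[:, None]
            feats.append(base * rng.normal(1.0, 0.1, size=(1, d)) + rng.normal(0, 0.05, size=(T, d)))
            labels.append(label)
    return feats, labels


class TestSequenceToolClassifier:
    def config(self, **kw):
        defaults = dict(T=10, epochs=15, batch_size=5, seed=0)
        defaults.update(kw)
        return ClassifierConfig(**defaults)

    def test_defaults_match_training_protocol(self):
        cfg = ClassifierConfig()
        assert (cfg.T, cfg.feature_dim, cfg.recurrent_hidden) == (50, 128, 128)
        assert (cfg.dropout, cfg.learning_rate, cfg.batch_size, cfg.epochs) == (0.5, 1e-3, 5, 15)

    def test_training_reduces_loss_on_separable_data(self):
        feats, labels = make_separable_features(10)
        model = SequenceToolClassifier(feats, labels, self.config())
        results = model.fit()
        assert len(results.loss_history) == 15
        assert results.loss_history[-1] < results.loss_history[0]

    def test_zero_epochs_returns_initialization(self):
        feats, labels = make_separable_features(3)
        model = SequenceToolClassifier(feats, labels, self.config())
        before = model.lstm.W.copy()
        results = model.fit(epochs=0)
        np.testing.assert_array_equal(model.lstm.W, before)
        assert results.loss_history == []

    def test_single_class_training_rejected(self):
        feats, _ = make_separable_features(3)
        with pytest.raises(ValueError):
            SequenceToolClassifier(feats, [POSITIVE_CLASS] * len(feats), self.config())

    def test_deterministic_given_seed(self):
        feats, labels = make_separable_features(4)
        r1 = SequenceToolClassifier(feats, labels, self.config()).fit(epochs=3)
        r2 = SequenceToolClassifier(feats, labels, self.config()).fit(epochs=3)
        assert r1.loss_history == r2.loss_history

    def test_trained_model_predictions_are_causal(self):
        feats, labels = make_separable_features(5)
        model = SequenceToolClassifier(feats, labels, self.config())
        model.fit(epochs=3)
        psi = feats[0]
        k = 6
        tampered = psi.copy()
        tampered[k:] += 100.0
        p_full = model.predict_timesteps(model.aggregate_sequence(psi))
        p_tampered = model.predict_timesteps(model.aggregate_sequence(tampered))
        np.testing.assert_allclose(p_tampered[:k], p_full[:k], atol=1e-10)
        assert not np.allclose(p_tampered[k:], p_full[k:])

    def test_forward_loss_scales_with_class_weights_before_update(self):
        feats, labels = make_separable_features(3)
        from toolmotion import nn

        model = SequenceToolClassifier(feats, labels, self.config())
        X = np.stack([f for f in model.features])
        Xs = (X - model.feat_mean) / model.feat_std
        p = model._forward(Xs)
        base = nn.weighted_bce(p, model.y, (1.0, 1.0))
        doubled = nn.weighted_bce(p, model.y, (2.0, 2.0))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_clip_shorter_than_T_rejected(self):
        feats, labels = make_separable_features(3, T=5)
        with pytest.raises(ValueError):
            SequenceToolClassifier(feats, labels, self.config(T=10))

    def test_evaluate_and_summary(self):
        feats, labels = make_separable_features(10)
        results = SequenceToolClassifier(feats, labels, self.config()).fit()
        metrics = results.evaluate(feats, labels)
        assert metrics["accuracy"] > 0.8  # training-set fit on separable data
        assert "LSTM" in results.summary()
        with pytest.raises(ValueError):
            results.evaluate([], [])


class TestPerFrameBaseline:
    def test_learns_frame_separable_classes(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(1, 1, (200, 128)), rng.normal(-1, 1, (200, 128))])
        y = [POSITIVE_CLASS] * 200 + [NEGATIVE_CLASS] * 200
        results = PerFrameBaseline(X, y, ClassifierConfig(T=1, epochs=10, seed=0)).fit()
        assert results.evaluate(X, y)["accuracy"] > 0.9

    def test_empty_eval_rejected(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(1, 1, (10, 128)), rng.normal(-1, 1, (10, 128))])
        y = [POSITIVE_CLASS] * 10 + [NEGATIVE_CLASS] * 10
        results = PerFrameBaseline(X, y, ClassifierConfig(T=1, epochs=1, seed=0)).fit()
        with pytest.raises(ValueError):
            results.evaluate(np.empty((0, 128)), [])

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 128))
        with pytest.raises(ValueError):
            PerFrameBaseline(X, [POSITIVE_CLASS] * 10, ClassifierConfig(T=1))
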