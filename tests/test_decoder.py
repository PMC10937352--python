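"""The bidirectional LSTM decoder: gradients, training protocol, inference."""

import numpy as np
import pytest

from seegspeech.dataset import PAD_SAMPLES, WINDOW_SAMPLES
from seegspeech.decoder import (
    DecoderConfig,
    classify_syllable,
    init_params,
    loss_and_grads,
    predict_sequence,
    train,
    _walk,
)
from tests.test_dataset import make_segment


def separable_windows(n_per_class=120, n_classes=3, n_features=4, shift=3.0,
                      seed=0):
    """Windows whose class mean differs by `shift` sd in feature 0."""
    rng = np.random.default_rng(seed)
    X, Y, sessions = [], [], []
    for k in range(n_classes):
        x = rng.standard_normal((n_per_class, WINDOW_SAMPLES, n_features))
        x[:, :, 0] += k * shift
        y = np.zeros((n_per_class, n_classes))
        y[:, k] = 1.0
        X.append(x)
        Y.append(y)
        # spread examples over 4 synthetic sessions for session-wise validation
        sessions.extend([f"s{i % 4}" for i in range(n_per_class)])
    return np.concatenate(X), np.concatenate(Y), sessions


def small_config(**kw):
    defaults = dict(hidden_units=8, layers=1, dropout=0.0, batch_size=64,
                    max_epochs=15, patience=3, seed=0)
    defaults.update(kw)
    return DecoderConfig(**defaults)


class TestGradients:
    @pytest.mark.parametrize("bidirectional, layers", [(True, 2), (False, 1)])
    def test_backprop_matches_numerical_gradient(self, bidirectional, layers):
        rng = np.random.default_rng(7)
        cfg = DecoderConfig(hidden_units=4, layers=layers,
                            bidirectional=bidirectional, dropout=0.0, seed=0)
        X = rng.standard_normal((3, 6, 2))
        Y = rng.standard_normal((3, 3))
        params = init_params(2, 3, cfg, rng)
        _, grads = loss_and_grads(params, X, Y, cfg)
        eps = 1e-6
        for path, arr in _walk(params):
            g = grads
            for p in path:
                g = g[p]
            flat = arr.reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss_and_grads(params, X, Y, cfg)
                flat[idx] = orig - eps
                lm, _ = loss_and_grads(params, X, Y, cfg)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[idx]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-8)


class TestTrainingProtocol:
    def test_same_seed_identical_logs(self):
        X, Y, sessions = separable_windows(n_per_class=40)
        cfg = small_config(max_epochs=4, dropout=0.5)
        m1 = train(X, Y, sessions, cfg, "task")
        m2 = train(X, Y, sessions, cfg, "task")
        assert m1.training_log == m2.training_log
        for (p1, a1), (p2, a2) in zip(_walk(m1.params), _walk(m2.params)):
            assert p1 == p2
            assert np.array_equal(a1, a2)

    def test_early_stopping_restores_best_checkpoint(self):
        X, Y, sessions = separable_windows(n_per_class=60)
        model = train(X, Y, sessions, small_config(max_epochs=20), "task")
        val_losses = [e["val_loss"] for e in model.training_log]
        assert model.training_log[model.best_epoch]["val_loss"] == min(val_losses)

    def test_separable_data_learned(self):
        """Trivially separable windows are decoded nearly perfectly, and the
        argmax agrees with an independent logistic-regression oracle."""
        from sklearn.linear_model import LogisticRegression

        X, Y, sessions = separable_windows()
        model = train(X, Y, sessions, small_config(), "task")
        pred = np.argmax(model.predict(X), axis=1)
        truth = np.argmax(Y, axis=1)
        assert np.mean(pred == truth) > 0.95

        oracle = LogisticRegression(max_iter=1000)
        oracle.fit(X.reshape(len(X), -1), truth)
        agree = np.mean(pred == oracle.predict(X.reshape(len(X), -1)))
        assert agree >= 0.99

    def test_shuffled_labels_stay_at_chance(self):
        """No-signal null: accuracy within the 95% binomial band of chance and
        training loss not collapsing below the one-hot variance floor."""
        from scipy import stats

        rng = np.random.default_rng(11)
        X, Y, sessions = separable_windows(n_per_class=80, shift=0.0, seed=5)
        K = Y.shape[1]
        model = train(X, Y, sessions, small_config(max_epochs=8), "task")
        # fresh null draws for testing
        Xt = rng.standard_normal((200, WINDOW_SAMPLES, X.shape[2]))
        acc = np.mean(np.argmax(model.predict(Xt), axis=1)
                      == rng.integers(K, size=200))
        lo = stats.binom.ppf(0.025, 200, 1 / K) / 200
        hi = stats.binom.ppf(0.975, 200, 1 / K) / 200
        assert lo <= acc <= hi
        # MSE floor for one-hot targets at chance: mean_k p(1-p) = (K-1)/K^2
        floor = (K - 1) / K**2
        assert model.training_log[-1]["train_loss"] > 0.9 * floor

    def test_channel_mismatch_rejected(self):
        X, Y, sessions = separable_windows(n_per_class=30)
        model = train(X, Y, sessions, small_config(max_epochs=2), "task")
        bad = np.zeros((5, WINDOW_SAMPLES, X.shape[2] + 1))
        with pytest.raises(ValueError, match="features"):
            model.predict(bad)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((0, 40, 3)), np.zeros((0, 4)), [], small_config())


@pytest.fixture(scope="module")
def model():
    X, Y, sessions = separable_windows(n_per_class=30, n_features=6)
    return train(X, Y, sessions, small_config(max_epochs=3), "tone")


class TestInference:
    def test_equal_length_outputs(self, model):
        seg = make_segment(80)
        scores = predict_sequence(model, seg)
        assert scores.shape == (80, 3)

    def test_argmax_in_category_set(self, model):
        seg = make_segment(37, seed=9)
        scores = predict_sequence(model, seg)
        assert np.all((np.argmax(scores, axis=1) >= 0)
                      & (np.argmax(scores, axis=1) < 3))

    def test_inference_deterministic(self, model):
        seg = make_segment(40, seed=2)
        a = predict_sequence(model, seg)
        b = predict_sequence(model, seg)
        assert np.array_equal(a, b)


class TestClassifySyllable:
    def test_majority_vote(self):
        scores = np.zeros((60, 6))
        scores[:40, 2] = 1.0
        scores[40:, 5] = 2.0
        assert classify_syllable(scores) == 2

    def test_unanimous(self):
        scores = np.tile([0.1, 0.9, 0.0], (10, 1))
        assert classify_syllable(scores) == 1

    def test_tie_broken_by_summed_score(self):
        scores = np.zeros((60, 6))
        scores[:30, 2] = 0.6
        scores[30:, 5] = 0.9  # same vote count, higher summed score
        assert classify_syllable(scores) == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_syllable(np.zeros((0, 4)))
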