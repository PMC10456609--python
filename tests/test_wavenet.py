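"""Classifier architecture contracts: shapes, causality, gradients, determinism."""

import numpy as np
import pytest

from hrvnet.wavenet import (TrainingDivergedError, WavenetSpec, build_model,
                            flatten_dim)

TINY = WavenetSpec(input_len=9, n_blocks=2, filters=4, dense_units=6,
                   n_classes=3, dropout_rate=0.0)


class TestSpec:
    def test_default_dilations_are_powers_of_two_up_to_64(self):
        assert WavenetSpec(n_blocks=7).dilations == (1, 2, 4, 8, 16, 32, 64)

    @pytest.mark.parametrize("spec, width", [
        (WavenetSpec(), 576),
        (WavenetSpec(input_len=1, filters=1), 1),
        (WavenetSpec(input_len=12, filters=32), 384),
    ])
    def test_flatten_dim(self, spec, width):
        assert flatten_dim(spec) == width

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WavenetSpec(n_classes=1)
        with pytest.raises(ValueError):
            WavenetSpec(kernel_size=3)


class TestForward:
    def test_measured_flatten_width_matches_default_spec(self):
        model = build_model(WavenetSpec(), seed=0)
        stack = model.stack_activations(np.zeros((2, 9)))
        assert stack.reshape(2, -1).shape[1] == 576

    def test_probability_rows_sum_to_one(self, rng):
        model = build_model(WavenetSpec(n_blocks=3), seed=1)
        probs = model.predict_proba(rng.normal(size=(7, 9)))
        assert probs.shape == (7, 5)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_rows_give_identical_outputs(self, rng):
        model = build_model(TINY, seed=2)
        x = rng.normal(size=9)
        probs = model.predict_proba(np.stack([x, x]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_two_builds_same_seed_agree_exactly(self, rng):
        X = rng.normal(size=(5, 9))
        a = build_model(WavenetSpec(n_blocks=3), seed=9).predict_proba(X)
        b = build_model(WavenetSpec(n_blocks=3), seed=9).predict_proba(X)
        assert a.tobytes() == b.tobytes()

    def test_wrong_input_width_rejected(self):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(np.zeros((2, 7)))

    def test_causality_of_convolutional_stack(self, rng):
        # perturbing position t must not change stack activations before t
        model = build_model(WavenetSpec(n_blocks=3, filters=8,
                                        dropout_rate=0.0), seed=4)
        x = rng.normal(size=(1, 9))
        base = model.stack_activations(x)
        for t in range(9):
            xp = x.copy()
            xp[0, t] += 1.0
            diff = np.abs(model.stack_activations(xp) - base)[0]
            assert np.all(diff[:t] == 0.0), f"position {t} leaked backwards"

    def test_receptive_field_covers_full_input_with_seven_blocks(self, rng):
        # with kernel 2 and dilations 1..64 the last timestep must react
        # to a change at position 0
        model = build_model(WavenetSpec(n_blocks=7), seed=5)
        x = rng.normal(size=(1, 9))
        xp = x.copy()
        xp[0, 0] += 1.0
        diff = np.abs(model.stack_activations(xp) - model.stack_activations(x))
        assert diff[0, -1].max() > 0

    def test_parameter_count_is_regression_stable(self):
        assert build_model(WavenetSpec(), seed=0).n_params == 705477
        assert build_model(TINY, seed=0).n_params == 477


class TestGradients:
    @pytest.mark.parametrize("use_residual", [False, True])
    def test_analytic_gradients_match_finite_differences(self, use_residual,
                                                         rng):
        spec = WavenetSpec(input_len=9, n_blocks=2, filters=4, dense_units=6,
                           n_classes=3, dropout_rate=0.0,
                           use_residual=use_residual)
        model = build_model(spec, seed=3)
        X = rng.standard_normal((4, 9))
        y = np.array([0, 1, 2, 1])
        _, grads = model.loss_and_gradients(X, y)
        eps = 1e-6
        for name, p in model.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = model.loss_and_gradients(X, y)
            p[idx] = orig - eps
            lm, _ = model.loss_and_gradients(X, y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, abs=1e-5), name


class TestTraining:
    @staticmethod
    def _toy_data(rng, n=60):
        y = rng.integers(0, 3, n)
        X = rng.normal(size=(n, 9)) * 0.3
        X[:, 0] += y  # linearly separable on the first feature
        return X, y

    def test_loss_decreases_on_separable_data(self, rng):
        X, y = self._toy_data(rng)
        model = build_model(TINY, seed=0)
        hist = model.fit(X, y, epochs=30, batch_size=16, learning_rate=0.01,
                         seed=1)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.train_acc[-1] >= 0.95

    def test_zero_epochs_leaves_weights_untouched(self, rng):
        X, y = self._toy_data(rng)
        model = build_model(TINY, seed=0)
        before = {k: v.copy() for k, v in model.params.items()}
        hist = model.fit(X, y, epochs=0, batch_size=16, learning_rate=0.01)
        assert hist.train_loss == []
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_training_is_bit_deterministic(self, rng):
        X, y = self._toy_data(rng)
        losses = []
        for _ in range(2):
            model = build_model(WavenetSpec(n_blocks=2, filters=4,
                                            dense_units=6, n_classes=3),
                                seed=5)
            hist = model.fit(X, y, epochs=5, batch_size=16,
                             learning_rate=0.01, seed=7)
            losses.append(hist.train_loss[-1])
        assert losses[0] == losses[1]

    def test_divergence_raises_with_diagnostic(self, rng):
        X, y = self._toy_data(rng)
        model = build_model(TINY, seed=0)
        with pytest.raises(TrainingDivergedError, match="lr="):
            model.fit(X * 1e308, y, epochs=3, batch_size=16,
                      learning_rate=1e10, seed=1)

    def test_weight_round_trip(self, tmp_path, rng):
        X, _ = self._toy_data(rng)
        model = build_model(TINY, seed=6)
        path = tmp_path / "w.npz"
        model.save_weights(path)
        other = build_model(TINY, seed=99)
        other.load_weights(path)
        np.testing.assert_array_equal(model.predict_proba(X),
                                      other.predict_proba(X))
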