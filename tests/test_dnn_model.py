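"""MLP construction, training dynamics, and activation recording."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from ncbl.dnn_model import (
    MLPSpec,
    TrainedMLP,
    activations,
    build_mlp,
    evaluate_accuracy,
    load_model,
    loss_and_gradients,
    save_model,
    train,
)
from ncbl.synthetic_data import GeneratorConfig, generate_dataset, split_dataset


def tiny_spec(**kwargs):
    defaults = dict(input_dim=6, hidden_sizes=(5, 4), output_dim=3,
                    dropout_keep=1.0, l2_penalty=1e-3)
    defaults.update(kwargs)
    return MLPSpec(**defaults)


class TestBuildMLP:
    def test_reference_architecture_shapes(self):
        """3072 -> 400/200/100/50/20 -> 10 chains six weight matrices."""
        spec = MLPSpec(input_dim=3072, hidden_sizes=(400, 200, 100, 50, 20),
                       output_dim=10)
        model = build_mlp(spec, seed=0)
        shapes = [w.shape for w in model.weights]
        assert shapes == [(3072, 400), (400, 200), (200, 100), (100, 50),
                          (50, 20), (20, 10)]
        assert all(b.shape == (s,) for b, s in zip(model.biases, spec.layer_sizes[1:]))

    def test_same_seed_bit_identical_weights(self):
        a, b = build_mlp(tiny_spec(), 9), build_mlp(tiny_spec(), 9)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_zero_weights_give_uniform_softmax(self, rng):
        model = build_mlp(tiny_spec(), 0)
        model = TrainedMLP(
            weights=[np.zeros_like(w) for w in model.weights],
            biases=[np.zeros_like(b) for b in model.biases],
            spec=model.spec,
        )
        out = model.forward(rng.random((7, 6)))
        assert np.allclose(out, 1.0 / 3.0)

    def test_inconsistent_shapes_rejected(self):
        spec = tiny_spec()
        model = build_mlp(spec, 0)
        with pytest.raises(ValueError, match="weight shape"):
            TrainedMLP(weights=[w.T for w in model.weights],
                       biases=model.biases, spec=spec)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradient vs central differences, 1e-5 relative."""
        model = build_mlp(tiny_spec(), 3)
        x = rng.random((8, 6))
        y = rng.integers(0, 3, size=8)
        loss, dWs, dbs = loss_and_gradients(model, x, y)
        eps = 1e-6
        for l in range(model.n_layers):
            for arr, grad in ((model.weights[l], dWs[l]), (model.biases[l], dbs[l])):
                flat = arr.ravel()
                idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
                for i in idx:
                    orig = flat[i]
                    flat[i] = orig + eps
                    lp, _, _ = loss_and_gradients(model, x, y)
                    flat[i] = orig - eps
                    lm, _, _ = loss_and_gradients(model, x, y)
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = grad.ravel()[i]
                    assert abs(num - ana) <= 1e-5 * max(1.0, abs(num))


class TestTrain:
    def test_zero_epochs_is_noop(self, four_class_set):
        data = split_dataset(four_class_set, (0.8, 0.1, 0.1), seed=0)
        spec = MLPSpec(input_dim=8 * 8 * 3, hidden_sizes=(10,), output_dim=4)
        model = build_mlp(spec, 1)
        out = train(model, data, epochs=0, seed=0)
        assert all(np.array_equal(a, b) for a, b in zip(out.weights, model.weights))
        assert out.training_log == []

    def test_accuracy_beats_chance_by_binomial_margin(self, trained_four_class):
        """Held-out accuracy clears the exact binomial 95% bound at 1/4."""
        model, data = trained_four_class
        test = data.split_subset("test")
        acc = evaluate_accuracy(model, test)
        n = test.n_samples
        # exact binomial upper 95% bound on accuracy under uniform guessing
        bound = stats.binom.ppf(0.95, n, 0.25) / n
        assert acc > bound

    def test_full_batch_loss_nonincreasing_without_dropout(self):
        cfg = GeneratorConfig(n_classes=2, n_per_class=20, image_shape=(4, 4, 1),
                              noise_sd=0.05, seed=4)
        data = split_dataset(generate_dataset(cfg), (1.0, 0.0, 0.0), seed=0)
        spec = MLPSpec(input_dim=16, hidden_sizes=(8,), output_dim=2,
                       dropout_keep=1.0, l2_penalty=0.0)
        model = train(build_mlp(spec, 0), data, epochs=30, batch_size=40,
                      learning_rate=0.01, seed=0)
        losses = [e["loss"] for e in model.training_log]
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_training_is_seed_reproducible(self, four_class_set):
        data = split_dataset(four_class_set, (0.8, 0.1, 0.1), seed=0)
        spec = MLPSpec(input_dim=8 * 8 * 3, hidden_sizes=(10,), output_dim=4)
        runs = [
            train(build_mlp(spec, 1), data, epochs=3, batch_size=32,
                  learning_rate=0.05, seed=7)
            for _ in range(2)
        ]
        assert all(
            np.array_equal(a, b) for a, b in zip(runs[0].weights, runs[1].weights)
        )

    def test_empty_train_split_rejected(self, four_class_set):
        data = split_dataset(four_class_set, (0.0, 0.5, 0.5), seed=0)
        model = build_mlp(MLPSpec(input_dim=8 * 8 * 3, hidden_sizes=(4,),
                                  output_dim=4), 0)
        with pytest.raises(ValueError, match="empty train split"):
            train(model, data, epochs=1)


class TestActivations:
    def test_output_rows_are_probability_vectors(self, trained_four_class):
        model, data = trained_four_class
        acts = activations(model, data.split_subset("test"), layer_id="output")
        assert np.allclose(acts.values.sum(axis=1), 1.0, atol=1e-6)

    def test_repeat_presentation_identical(self, trained_four_class):
        """Units output a fixed value for the same input: no dropout at read-out."""
        model, data = trained_four_class
        x = data.split_subset("test")
        a = activations(model, x, layer_id="last_hidden")
        b = activations(model, x, layer_id="last_hidden")
        assert np.array_equal(a.values, b.values)

    def test_hidden_activations_nonnegative(self, trained_four_class):
        model, data = trained_four_class
        for lid in range(1, model.n_layers):
            acts = activations(model, data.split_subset("test"), layer_id=lid)
            assert acts.values.min() >= 0.0

    def test_bad_layer_id_rejected(self, trained_four_class):
        model, data = trained_four_class
        with pytest.raises(ValueError, match="layer_id"):
            activations(model, data.split_subset("test"), layer_id=99)


class TestEvaluateAccuracy:
    def test_memorization_of_one_sample_per_class(self):
        cfg = GeneratorConfig(n_classes=3, n_per_class=1, image_shape=(4, 4, 1),
                              noise_sd=0.0, seed=8)
        data = generate_dataset(cfg)
        data = split_dataset(data, (1.0, 0.0, 0.0), seed=0)
        spec = MLPSpec(input_dim=16, hidden_sizes=(16,), output_dim=3,
                       dropout_keep=1.0, l2_penalty=0.0)
        model = train(build_mlp(spec, 0), data, epochs=300, batch_size=3,
                      learning_rate=0.5, seed=0)
        assert evaluate_accuracy(model, data) == 1.0

    def test_uniform_prediction_ties_to_class_zero(self, four_class_set):
        spec = MLPSpec(input_dim=8 * 8 * 3, hidden_sizes=(5,), output_dim=4)
        model = build_mlp(spec, 0)
        zero = TrainedMLP(
            weights=[np.zeros_like(w) for w in model.weights],
            biases=[np.zeros_like(b) for b in model.biases],
            spec=spec,
        )
        # all predictions fall on class 0, so accuracy equals class 0's share
        acc = evaluate_accuracy(zero, four_class_set)
        assert acc == pytest.approx(0.25)

    def test_label_subset_restricts_samples_not_outputs(self, trained_four_class):
        model, data = trained_four_class
        test = data.split_subset("test")
        acc_pair = evaluate_accuracy(model, test, label_subset=[0, 1])
        mask = np.isin(test.labels, [0, 1])
        manual = np.mean(model.predict(test.flattened()[mask]) == test.labels[mask])
        assert acc_pair == pytest.approx(manual)

    def test_empty_after_filter_rejected(self, trained_four_class):
        model, data = trained_four_class
        with pytest.raises(ValueError, match="no samples"):
            evaluate_accuracy(model, data.split_subset("test"), label_subset=[99])


def test_model_round_trip_is_bit_exact(tmp_path, trained_four_class):
    model, _ = trained_four_class
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert all(np.array_equal(a, b) for a, b in zip(model.weights, back.weights))
    assert all(np.array_equal(a, b) for a, b in zip(model.biases, back.biases))
    assert back.spec == model.spec
    assert back.training_log == model.training_log


def test_training_log_csv_columns(tmp_path, trained_four_class):
    import pandas as pd

    from ncbl.dnn_model import save_training_log_csv

    model, _ = trained_four_class
    save_training_log_csv(model, tmp_path / "log.csv")
    df = pd.read_csv(tmp_path / "log.csv")
    assert list(df.columns) == ["epoch", "train_acc", "val_acc", "loss"]
    assert len(df) == len(model.training_log)
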