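"""Shared fixtures: small generated datasets and a quickly trained model."""

from __future__ import annotations

import numpy as np
import pytest

from ncbl.dnn_model import MLPSpec, build_mlp, train
from ncbl.synthetic_data import GeneratorConfig, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def four_class_set():
    """Four well-separated classes, small images; deterministic."""
    cfg = GeneratorConfig(
        n_classes=4, n_per_class=60, image_shape=(8, 8, 3), noise_sd=0.05, seed=11
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def trained_four_class(four_class_set):
    """A small MLP trained on the four-class set (seconds)."""
    data = split_dataset(four_class_set, (0.75, 0.08, 0.17), seed=5)
    spec = MLPSpec(input_dim=8 * 8 * 3, hidden_sizes=(24, 12), output_dim=4)
    model = build_mlp(spec, seed=2)
    model = train(model, data, epochs=60, batch_size=32, learning_rate=0.1, seed=3)
    return model, data


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
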