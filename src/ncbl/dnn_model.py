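"""Dense feedforward classifier used as the in-silico brain.

A rectified-linear multilayer perceptron with a softmax read-out, trained by
mini-batch stochastic gradient descent on cross-entropy with an L2 penalty
and inverted dropout.  The forward/backward passes are implemented
explicitly so that downstream analyses (receptive-field backprojection in
particular) can rely on a known layer layout: weight ``W_l`` has shape
``(fan_in, fan_out)`` and the pre-activation is ``z_l = a_{l-1} @ W_l + b_l``.

Layer indexing convention: layer ``l`` (1-based) is the post-activation of
the ``l``-th weight matrix, so ``l = n_layers`` is the softmax output and
``l = n_layers - 1`` the last hidden layer.  The strings ``"output"`` and
``"last_hidden"`` are accepted aliases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ncbl.synthetic_data import LabeledImageSet

__all__ = [
    "MLPSpec",
    "TrainedMLP",
    "ActivationMatrix",
    "build_mlp",
    "train",
    "activations",
    "evaluate_accuracy",
    "loss_and_gradients",
    "save_model",
    "save_training_log_csv",
    "load_model",
]


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and regularization of the dense classifier."""

    input_dim: int
    hidden_sizes: tuple[int, ...]
    output_dim: int
    dropout_keep: float = 0.8
    l2_penalty: float = 1e-4

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be positive")
        if len(self.hidden_sizes) < 1:
            raise ValueError("need at least one hidden layer")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must lie in (0, 1]")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be nonnegative")
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_sizes, self.output_dim)

    @property
    def n_layers(self) -> int:
        """Number of weight layers (hidden layers + output)."""
        return len(self.hidden_sizes) + 1


def reference_spec(input_dim: int = 3072, output_dim: int = 10) -> MLPSpec:
    """The reference architecture: five hidden layers 400/200/100/50/20."""
    return MLPSpec(input_dim=input_dim, hidden_sizes=(400, 200, 100, 50, 20),
                   output_dim=output_dim)


@dataclass
class TrainedMLP:
    """Weights, biases, and the training history of the classifier."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    spec: MLPSpec
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.spec.layer_sizes
        if len(self.weights) != self.spec.n_layers or len(self.biases) != self.spec.n_layers:
            raise ValueError("weight/bias count does not match spec")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l], sizes[l + 1]):
                raise ValueError(
                    f"layer {l}: weight shape {w.shape} != {(sizes[l], sizes[l + 1])}"
                )
            if b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l}: bias shape {b.shape}")

    @property
    def n_layers(self) -> int:
        return self.spec.n_layers

    def forward(self, x: np.ndarray, return_hidden: bool = False):
        """Deterministic forward pass (dropout disabled).

        Returns the softmax output, or ``(output, [a_1 ... a_L])`` with every
        post-activation when ``return_hidden`` is set.
        """
        a = np.asarray(x, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        hidden: list[np.ndarray] = []
        for l in range(self.n_layers - 1):
            a = np.maximum(a @ self.weights[l] + self.biases[l], 0.0)
            hidden.append(a)
        out = _softmax(a @ self.weights[-1] + self.biases[-1])
        hidden.append(out)
        return (out, hidden) if return_hidden else out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class per row; ties broken toward the lowest class index."""
        return np.argmax(self.forward(x), axis=1)


@dataclass
class ActivationMatrix:
    """Trials x units activations from one recorded layer."""

    values: np.ndarray
    layer_id: int
    trial_labels: np.ndarray
    trial_sublabels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trial_labels = np.asarray(self.trial_labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be trials x units")
        if self.values.shape[0] != self.trial_labels.shape[0]:
            raise ValueError("row count must equal number of presented stimuli")
        if self.trial_sublabels is not None:
            self.trial_sublabels = np.asarray(self.trial_sublabels, dtype=int)
            if self.trial_sublabels.shape[0] != self.values.shape[0]:
                raise ValueError("sublabel length mismatch")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_mlp(spec: MLPSpec, seed: int) -> TrainedMLP:
    """Seeded He-style initialization: W ~ N(0, 2/fan_in), zero biases."""
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[l]), size=(sizes[l], sizes[l + 1]))
        for l in range(spec.n_layers)
    ]
    biases = [np.zeros(sizes[l + 1]) for l in range(spec.n_layers)]
    return TrainedMLP(weights=weights, biases=biases, spec=spec)


def loss_and_gradients(
    model: TrainedMLP,
    x: np.ndarray,
    y: np.ndarray,
    dropout_masks: list[np.ndarray] | None = None,
):
    """Cross-entropy + L2 loss and its analytic gradients.

    ``dropout_masks`` are pre-scaled inverted-dropout masks, one per hidden
    layer (None disables dropout).  Returns ``(loss, dWs, dbs)``.
    """
    n = x.shape[0]
    L = model.n_layers
    acts = [np.asarray(x, dtype=float)]
    for l in range(L - 1):
        a = np.maximum(acts[-1] @ model.weights[l] + model.biases[l], 0.0)
        if dropout_masks is not None:
            a = a * dropout_masks[l]
        acts.append(a)
    probs = _softmax(acts[-1] @ model.weights[-1] + model.biases[-1])

    lam = model.spec.l2_penalty
    ce = -np.mean(np.log(np.clip(probs[np.arange(n), y], 1e-12, None)))
    loss = ce + 0.5 * lam * sum(float(np.sum(w * w)) for w in model.weights)

    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    dWs: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    dbs: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    for l in range(L - 1, -1, -1):
        dWs[l] = acts[l].T @ delta + lam * model.weights[l]
        dbs[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ model.weights[l].T
            if dropout_masks is not None:
                delta = delta * dropout_masks[l - 1]
            delta = delta * (acts[l] > 0)
    return loss, dWs, dbs


def train(
    model: TrainedMLP,
    data: LabeledImageSet,
    epochs: int,
    batch_size: int = 512,
    learning_rate: float = 0.05,
    lr_decay: float = 1.0,
    seed: int = 0,
) -> TrainedMLP:
    """Mini-batch SGD on the ``train`` split; returns a new trained model.

    The step size in epoch ``t`` is ``learning_rate * lr_decay**t``; a decay
    slightly below 1 guards against the late-training divergence plain SGD
    is prone to on easy tasks.  Dropout uses inverted scaling (activations
    divided by the keep probability at train time) so inference needs no
    rescaling.  Seeded shuffling and mask draws make the run reproducible.
    """
    if data.split is None:
        raise ValueError("dataset has no split tags; call split_dataset first")
    train_set = data.split_subset("train")
    if train_set.n_samples == 0:
        raise ValueError("empty train split")
    has_val = np.any(data.split == "val")
    val_set = data.split_subset("val") if has_val else None

    x = train_set.flattened()
    y = train_set.labels
    if x.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"flattened image dim {x.shape[1]} != model input_dim {model.spec.input_dim}"
        )

    rng = np.random.default_rng(seed)
    weights = [w.copy() for w in model.weights]
    biases = [b.copy() for b in model.biases]
    current = TrainedMLP(weights=weights, biases=biases, spec=model.spec)
    keep = model.spec.dropout_keep
    log: list[dict] = []

    n = x.shape[0]
    for epoch in range(epochs):
        lr = learning_rate * lr_decay**epoch
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            masks = None
            if keep < 1.0:
                masks = [
                    (rng.random((xb.shape[0], h)) < keep) / keep
                    for h in model.spec.hidden_sizes
                ]
            loss, dWs, dbs = loss_and_gradients(current, xb, yb, masks)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}; "
                    f"reduce the learning rate (currently {learning_rate})"
                )
            for l in range(current.n_layers):
                weights[l] -= lr * dWs[l]
                biases[l] -= lr * dbs[l]
            epoch_loss += loss
            n_batches += 1
        entry = {
            "epoch": epoch,
            "loss": epoch_loss / max(n_batches, 1),
            "train_acc": float(np.mean(current.predict(x) == y)),
        }
        if val_set is not None and val_set.n_samples:
            entry["val_acc"] = float(
                np.mean(current.predict(val_set.flattened()) == val_set.labels)
            )
        log.append(entry)

    return TrainedMLP(
        weights=weights, biases=biases, spec=model.spec,
        training_log=model.training_log + log,
    )


def _resolve_layer_id(model: TrainedMLP, layer_id: int | str) -> int:
    if layer_id == "output":
        return model.n_layers
    if layer_id == "last_hidden":
        return model.n_layers - 1
    layer_id = int(layer_id)
    if not 1 <= layer_id <= model.n_layers:
        raise ValueError(
            f"layer_id must be in [1, {model.n_layers}] (or 'output'/'last_hidden')"
        )
    return layer_id


def activations(
    model: TrainedMLP,
    data: LabeledImageSet | np.ndarray,
    layer_id: int | str = "output",
    labels: np.ndarray | None = None,
    sublabels: np.ndarray | None = None,
) -> ActivationMatrix:
    """Record one layer's response to a stimulus set (dropout off).

    Rows follow input order; for the output layer each row is a softmax
    probability vector, for hidden layers rectified-linear activations.
    """
    if isinstance(data, LabeledImageSet):
        x = data.flattened()
        labels = data.labels
        sublabels = data.sublabels
    else:
        x = np.asarray(data, dtype=float)
        if x.ndim > 2:
            x = x.reshape(x.shape[0], -1)
        if labels is None:
            labels = np.zeros(x.shape[0], dtype=int)
    lid = _resolve_layer_id(model, layer_id)
    _, hidden = model.forward(x, return_hidden=True)
    return ActivationMatrix(
        values=hidden[lid - 1],
        layer_id=lid,
        trial_labels=labels,
        trial_sublabels=sublabels,
    )


def evaluate_accuracy(
    model: TrainedMLP,
    data: LabeledImageSet,
    label_subset: Sequence[int] | None = None,
) -> float:
    """Argmax-class accuracy, optionally restricted to samples of some classes.

    The prediction is always over all K outputs; ``label_subset`` only
    filters which samples are scored (e.g. pair-restricted accuracy on a
    confusable cat/dog analog).
    """
    if data.n_samples == 0:
        raise ValueError("empty evaluation set")
    mask = np.ones(data.n_samples, dtype=bool)
    if label_subset is not None:
        mask = np.isin(data.labels, list(label_subset))
        if not mask.any():
            raise ValueError("no samples left after class filtering")
    preds = model.predict(data.flattened()[mask])
    return float(np.mean(preds == data.labels[mask]))


# ---------------------------------------------------------------------------
# single-file weight container: named arrays + JSON header


def save_model(model: TrainedMLP, path: str | Path) -> None:
    """Write weights/biases and the spec to one ``.npz`` file (lossless)."""
    header = {
        "input_dim": model.spec.input_dim,
        "hidden_sizes": list(model.spec.hidden_sizes),
        "output_dim": model.spec.output_dim,
        "dropout_keep": model.spec.dropout_keep,
        "l2_penalty": model.spec.l2_penalty,
        "training_log": model.training_log,
    }
    arrays = {f"W{l}": w for l, w in enumerate(model.weights)}
    arrays.update({f"b{l}": b for l, b in enumerate(model.biases)})
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def save_training_log_csv(model: TrainedMLP, path: str | Path) -> None:
    """Write the per-epoch log as CSV (epoch, train_acc, val_acc, loss)."""
    import pandas as pd

    df = pd.DataFrame(model.training_log)
    cols = [c for c in ("epoch", "train_acc", "val_acc", "loss") if c in df.columns]
    df[cols].to_csv(path, index=False)


def load_model(path: str | Path) -> TrainedMLP:
    """Bit-exact round trip of :func:`save_model`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"].tobytes()).decode())
        spec = MLPSpec(
            input_dim=header["input_dim"],
            hidden_sizes=tuple(header["hidden_sizes"]),
            output_dim=header["output_dim"],
            dropout_keep=header["dropout_keep"],
            l2_penalty=header["l2_penalty"],
        )
        weights = [data[f"W{l}"] for l in range(spec.n_layers)]
        biases = [data[f"b{l}"] for l in range(spec.n_layers)]
    return TrainedMLP(weights=weights, biases=biases, spec=spec,
                      training_log=header["training_log"])
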