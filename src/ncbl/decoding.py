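"""Binary linear decoding and chance-level accounting (baseline inflation).

A linear support-vector machine trained on one-vs-rest labels reads out a
"recorded" layer's activity.  The point of the scenario: the decoder's
chance level is 1/2 while the network's own task has chance 1/K, so the
decoder's raw accuracy can exceed the network's K-way accuracy even when
it carries no additional information.  ``compare_baselines`` makes both
baselines explicit and flags exactly this inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from ncbl.dnn_model import ActivationMatrix

__all__ = [
    "DecoderResult",
    "DecodingSet",
    "BaselineComparison",
    "build_decoding_set",
    "train_linear_decoder",
    "evaluate_decoder",
    "chance_level",
    "compare_baselines",
]


@dataclass(frozen=True)
class DecodingSet:
    """Training features/labels plus held-out positive-class features."""

    train_features: np.ndarray
    train_labels: np.ndarray  # 1 = positive class, 0 = rest
    heldout_features: np.ndarray
    positive_class: int


@dataclass(frozen=True)
class DecoderResult:
    """A fitted binary linear decoder with its evaluation bookkeeping."""

    accuracy: float
    chance: float
    n_train: int
    n_test: int
    positive_class: int
    weights: np.ndarray
    bias: float

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.decision_function(features) > 0).astype(int)


def build_decoding_set(
    acts: ActivationMatrix,
    positive_class: int,
    n_positive_train: int,
    n_per_negative_class: int,
    n_positive_heldout: int | None = None,
    seed: int = 0,
) -> DecodingSet:
    """Assemble a positive-vs-rest training set and held-out positives.

    Membership is deterministic for a given seed: trials of each class are
    shuffled once and the first ``n`` taken.  The held-out set contains only
    positive-class trials, mirroring an evaluation of decoder sensitivity on
    the target class.
    """
    rng = np.random.default_rng(seed)
    labels = acts.trial_labels
    classes = np.unique(labels)
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class} absent from data")
    if n_per_negative_class < 1:
        raise ValueError("need at least one negative sample per class")

    deficits = {}
    pos_idx = np.flatnonzero(labels == positive_class)
    pos_idx = pos_idx[rng.permutation(len(pos_idx))]
    need_pos = n_positive_train + (n_positive_heldout or 1)
    if len(pos_idx) < need_pos:
        deficits[int(positive_class)] = need_pos - len(pos_idx)

    neg_parts = []
    for c in classes:
        if c == positive_class:
            continue
        idx = np.flatnonzero(labels == c)
        if len(idx) < n_per_negative_class:
            deficits[int(c)] = n_per_negative_class - len(idx)
            continue
        idx = idx[rng.permutation(len(idx))]
        neg_parts.append(idx[:n_per_negative_class])
    if deficits:
        raise ValueError(f"insufficient trials; per-class deficit: {deficits}")

    train_pos = pos_idx[:n_positive_train]
    heldout = pos_idx[n_positive_train:]
    if n_positive_heldout is not None:
        heldout = heldout[:n_positive_heldout]
    neg = np.concatenate(neg_parts)
    train_idx = np.concatenate([train_pos, neg])
    return DecodingSet(
        train_features=acts.values[train_idx],
        train_labels=(labels[train_idx] == positive_class).astype(int),
        heldout_features=acts.values[heldout],
        positive_class=int(positive_class),
    )


def train_linear_decoder(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    max_iter: int = 50000,
) -> "LinearSVC":
    """Fit a maximum-margin linear classifier (hinge loss, L2, strength 1/C).

    Features are used raw, unstandardized.  The solver is deterministic for
    fixed inputs.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set must contain both labels")
    clf = LinearSVC(C=C, loss="hinge", max_iter=max_iter, random_state=0)
    clf.fit(np.asarray(features), labels)
    return clf


def evaluate_decoder(
    clf: "LinearSVC",
    heldout_features: np.ndarray,
    heldout_labels: np.ndarray | int,
    n_train: int,
    positive_class: int,
) -> DecoderResult:
    """Score the decoder on held-out features (labels may be a constant)."""
    heldout_features = np.asarray(heldout_features)
    if np.isscalar(heldout_labels):
        heldout_labels = np.full(len(heldout_features), heldout_labels, dtype=int)
    preds = clf.predict(heldout_features)
    return DecoderResult(
        accuracy=float(np.mean(preds == heldout_labels)),
        chance=chance_level(2),
        n_train=n_train,
        n_test=len(heldout_features),
        positive_class=positive_class,
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
    )


def chance_level(n_labels: int) -> float:
    """Expected accuracy of uniform guessing over ``n_labels`` options."""
    if n_labels < 2:
        raise ValueError("a classification task needs at least 2 labels")
    return 1.0 / n_labels


@dataclass(frozen=True)
class BaselineComparison:
    """Side-by-side accounting of two accuracies against their own baselines."""

    network_accuracy: float
    network_chance: float
    network_excess: float
    decoder_accuracy: float
    decoder_chance: float
    decoder_excess: float
    inflation_flag: bool

    def as_dict(self) -> dict:
        return {
            "network_accuracy": self.network_accuracy,
            "network_chance": self.network_chance,
            "network_excess": self.network_excess,
            "decoder_accuracy": self.decoder_accuracy,
            "decoder_chance": self.decoder_chance,
            "decoder_excess": self.decoder_excess,
            "inflation_flag": self.inflation_flag,
        }


def compare_baselines(
    network_accuracy: float,
    network_n_labels: int,
    decoder_accuracy: float,
    decoder_n_labels: int,
) -> BaselineComparison:
    """Report both accuracies with their chance levels and excesses.

    The inflation flag is raised when the decoder's raw accuracy exceeds the
    network's although the two tasks have different chance levels — the
    comparison a careless reading would make without baseline accounting.
    """
    for a in (network_accuracy, decoder_accuracy):
        if not 0.0 <= a <= 1.0:
            raise ValueError("accuracies must lie in [0, 1]")
    net_chance = chance_level(network_n_labels)
    dec_chance = chance_level(decoder_n_labels)
    flag = decoder_accuracy > network_accuracy and dec_chance != net_chance
    return BaselineComparison(
        network_accuracy=network_accuracy,
        network_chance=net_chance,
        network_excess=network_accuracy - net_chance,
        decoder_accuracy=decoder_accuracy,
        decoder_chance=dec_chance,
        decoder_excess=decoder_accuracy - dec_chance,
        inflation_flag=bool(flag),
    )
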