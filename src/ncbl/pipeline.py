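"""End-to-end scenario runs: generate -> train -> analyze -> report.

Each scenario function is pure given its configuration and master seed:
all randomness flows from named sub-seeds derived from the master seed by a
counter-free hashing scheme, so adding one scenario never shifts another's
random stream, and re-running a configuration reproduces every output
bit-for-bit.

The default configurations are miniature analogs of the full-scale study
design: smaller images, fewer samples and shorter training, chosen so each
scenario's qualitative effect is demonstrated in seconds to minutes on one
CPU.  Every knob is exposed through :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from ncbl import __version__
from ncbl.confound_rf import (
    footprint_mask,
    reconstruct_receptive_field,
    region_saliency,
    rf_repredict,
)
from ncbl.decoding import (
    build_decoding_set,
    chance_level,
    compare_baselines,
    evaluate_decoder,
    train_linear_decoder,
)
from ncbl.dnn_model import (
    MLPSpec,
    TrainedMLP,
    activations,
    build_mlp,
    evaluate_accuracy,
    train,
)
from ncbl.noise_corr import (
    UnitActivityMatrix,
    apply_internal_rhythm,
    estimate_within_unit_variability,
    make_population_model,
    pairwise_noise_correlation,
    sample_neurons,
)
from ncbl.selectivity import excluded_class_analysis, selectivity_profile
from ncbl.synthetic_data import (
    GeneratorConfig,
    LabeledImageSet,
    Logo,
    generate_dataset,
    inject_logo,
    split_dataset,
)

__all__ = [
    "RunConfig",
    "TrainingConfig",
    "derive_seed",
    "run_scenario",
    "run_scenario_1",
    "run_scenario_2",
    "run_scenario_3",
    "run_scenario_4_grain",
    "run_scenario_4_rhythm",
    "make_logos",
    "trained_model_on",
]

SCENARIOS = ("s1", "s2", "s3", "s4_grain", "s4_rhythm")
SPLIT_FRACTIONS = (0.75, 0.08, 0.17)


def derive_seed(master_seed: int, name: str) -> int:
    """Stable named sub-seed below 2^31, independent of call order."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and architecture settings for the in-silico brain."""

    hidden_sizes: tuple[int, ...] = (48, 24)
    epochs: int = 120
    batch_size: int = 64
    learning_rate: float = 0.1
    lr_decay: float = 1.0
    dropout_keep: float = 0.8
    l2_penalty: float = 1e-4


def trained_model_on(
    data: LabeledImageSet, training: TrainingConfig, master_seed: int, tag: str
) -> tuple[TrainedMLP, LabeledImageSet]:
    """Split, build, and train a model on a dataset with named sub-seeds."""
    split = split_dataset(data, SPLIT_FRACTIONS, seed=derive_seed(master_seed, f"{tag}/split"))
    spec = MLPSpec(
        input_dim=int(np.prod(data.image_shape)),
        hidden_sizes=training.hidden_sizes,
        output_dim=data.n_classes,
        dropout_keep=training.dropout_keep,
        l2_penalty=training.l2_penalty,
    )
    model = build_mlp(spec, seed=derive_seed(master_seed, f"{tag}/init"))
    return train(
        model,
        split,
        epochs=training.epochs,
        batch_size=training.batch_size,
        learning_rate=training.learning_rate,
        lr_decay=training.lr_decay,
        seed=derive_seed(master_seed, f"{tag}/train"),
    ), split


# ---------------------------------------------------------------------------
# scenario 1: suboptimal feature selectivity


def run_scenario_1(
    generator: GeneratorConfig | None = None,
    training: TrainingConfig | None = None,
    unit_id: int = 0,
    excluded_class: int = 0,
    master_seed: int = 0,
) -> dict[str, Any]:
    """Train on a set with a confusable pair; exclude the unit's own class.

    With the tuned class present the unit's top regression feature is its
    own class; with it excluded, the confusable partner takes over — the
    suboptimal-selectivity event.
    """
    generator = generator or GeneratorConfig(
        n_classes=6,
        n_per_class=120,
        image_shape=(12, 12, 3),
        noise_sd=0.08,
        confusable_pairs=((0, 1),),
        shared_weight=0.8,
        seed=derive_seed(master_seed, "s1/data"),
    )
    training = training or TrainingConfig()
    data = generate_dataset(generator)
    model, split = trained_model_on(data, training, master_seed, "s1")
    test = split.split_subset("test")
    acts = activations(model, test, layer_id="output")
    profile = selectivity_profile(acts, unit_id)
    report = excluded_class_analysis(acts, unit_id, excluded_class)
    return {
        "scenario": "s1",
        "unit_id": unit_id,
        "excluded_class": excluded_class,
        "profile_class_ids": profile.class_ids.tolist(),
        "profile_means": profile.class_means.tolist(),
        "top_feature_full": report.top_feature_full,
        "top_feature_reduced": report.top_feature_reduced,
        "selectivity_changed": report.selectivity_changed,
        "full_coefficients": report.full.coefficients.tolist(),
        "full_p_values": report.full.p_values.tolist(),
        "full_explained_variance": report.full.explained_variance.tolist(),
        "reduced_class_ids": report.reduced.class_ids.tolist(),
        "reduced_coefficients": report.reduced.coefficients.tolist(),
        "test_accuracy": evaluate_accuracy(model, test),
    }


# ---------------------------------------------------------------------------
# scenario 2: irrelevant (confound) feature selectivity


def make_logos(
    image_shape: tuple[int, int, int],
    patch_size: int = 3,
    opacity: float = 0.2,
    seed: int = 0,
) -> tuple[Logo, Logo]:
    """Two independent seeded logo patches at lower-left and lower-right."""
    H, W, C = image_shape
    rng = np.random.default_rng(seed)
    margin = 1
    anchors = [
        (H - patch_size - margin, margin),              # lower left
        (H - patch_size - margin, W - patch_size - margin),  # lower right
    ]
    # bright patches: the blend consistently raises footprint pixels, so the
    # learned logo-detector weights share one sign and stand out in the map
    logos = tuple(
        Logo(
            patch=rng.uniform(0.7, 1.0, size=(patch_size, patch_size, C)),
            anchor=anchor,
            opacity=opacity,
        )
        for anchor in anchors
    )
    return logos  # type: ignore[return-value]


def run_scenario_2(
    generator: GeneratorConfig | None = None,
    training: TrainingConfig | None = None,
    target_classes: tuple[int, int] = (0, 1),
    patch_size: int = 4,
    opacity: float = 0.2,
    master_seed: int = 0,
) -> dict[str, Any]:
    """Pair accuracy and receptive-field saliency with and without logos.

    The confusable pair is nearly inseparable from class content alone;
    injected logos act as a shortcut feature, raising pair accuracy, and
    backprojected receptive fields concentrate on the logo footprints.
    """
    generator = generator or GeneratorConfig(
        n_classes=6,
        n_per_class=120,
        image_shape=(12, 12, 3),
        noise_sd=0.12,
        confusable_pairs=(tuple(target_classes),),
        shared_weight=0.95,
        seed=derive_seed(master_seed, "s2/data"),
    )
    training = training or TrainingConfig(hidden_sizes=(64, 32), epochs=250)
    clean = generate_dataset(generator)
    logos = make_logos(
        generator.image_shape,
        patch_size=patch_size,
        opacity=opacity,
        seed=derive_seed(master_seed, "s2/logos"),
    )
    modified = inject_logo(clean, list(target_classes), list(logos))

    clean_model, clean_split = trained_model_on(clean, training, master_seed, "s2")
    logo_model, logo_split = trained_model_on(modified, training, master_seed, "s2")

    pair = list(target_classes)
    acc_clean = evaluate_accuracy(clean_model, clean_split.split_subset("test"), pair)
    acc_logo = evaluate_accuracy(logo_model, logo_split.split_subset("test"), pair)

    shape = generator.image_shape
    saliencies = {}
    for model_name, model in (("clean", clean_model), ("logo", logo_model)):
        for c, logo in zip(target_classes, logos):
            rf = reconstruct_receptive_field(model, c, shape)
            mask = footprint_mask(shape, *logo.footprint(shape))
            saliencies[f"{model_name}_class{c}"] = region_saliency(rf, mask)

    maps = [reconstruct_receptive_field(logo_model, c, shape) for c in range(clean.n_classes)]
    _, n_correct = rf_repredict(logo_model, maps)

    return {
        "scenario": "s2",
        "target_classes": list(target_classes),
        "pair_accuracy_clean": acc_clean,
        "pair_accuracy_logo": acc_logo,
        "saliency": saliencies,
        "rf_repredict_correct": n_correct,
        "n_classes": clean.n_classes,
        "logo_anchors": [list(l.anchor) for l in logos],
        "patch_size": patch_size,
        "opacity": opacity,
    }


# ---------------------------------------------------------------------------
# scenario 3: decoding-baseline inflation


def run_scenario_3(
    generator: GeneratorConfig | None = None,
    training: TrainingConfig | None = None,
    positive_class: int = 3,
    n_positive_train: int = 100,
    n_per_negative_class: int = 11,
    C: float = 1.0,
    master_seed: int = 0,
) -> dict[str, Any]:
    """Binary linear-SVM read-out vs. the network's own K-way accuracy.

    Mirrors a cat-vs-rest decoding study on last-hidden-layer activity: the
    decoder's raw accuracy, with chance 1/2, can exceed the network's K-way
    accuracy on the positive class, whose chance is 1/K.
    """
    generator = generator or GeneratorConfig(
        n_classes=10,
        n_per_class=700,
        image_shape=(12, 12, 3),
        noise_sd=0.1,
        template_amplitude=0.2,
        confusable_pairs=((0, 1), (2, 3), (4, 5), (6, 7), (8, 9)),
        shared_weight=0.93,
        seed=derive_seed(master_seed, "s3/data"),
    )
    training = training or TrainingConfig(epochs=40, learning_rate=0.05, lr_decay=0.97)
    data = generate_dataset(generator)
    model, split = trained_model_on(data, training, master_seed, "s3")
    test = split.split_subset("test")

    acts = activations(model, test, layer_id="last_hidden")
    dset = build_decoding_set(
        acts,
        positive_class=positive_class,
        n_positive_train=n_positive_train,
        n_per_negative_class=n_per_negative_class,
        seed=derive_seed(master_seed, "s3/decoding_set"),
    )
    clf = train_linear_decoder(dset.train_features, dset.train_labels, C=C)
    decoder = evaluate_decoder(
        clf,
        dset.heldout_features,
        1,
        n_train=len(dset.train_labels),
        positive_class=positive_class,
    )
    network_acc = evaluate_accuracy(model, test, [positive_class])
    comparison = compare_baselines(
        network_acc, data.n_classes, decoder.accuracy, 2
    )
    return {
        "scenario": "s3",
        "positive_class": positive_class,
        "network_accuracy": network_acc,
        "network_chance": chance_level(data.n_classes),
        "decoder_accuracy": decoder.accuracy,
        "decoder_chance": chance_level(2),
        "n_heldout": decoder.n_test,
        **{f"comparison_{k}": v for k, v in comparison.as_dict().items()},
    }


# ---------------------------------------------------------------------------
# scenario 4: noise-correlation overestimation


def _scenario4_traces(
    generator: GeneratorConfig,
    training: TrainingConfig,
    m_stage1: int,
    m_stage2: int,
    focus_unit: int,
    master_seed: int,
) -> tuple[UnitActivityMatrix, UnitActivityMatrix]:
    """Stage-one per-unit traces and stage-two focus-class traces.

    Stage one presents each unit fresh noisy images of its own tuned class
    (cycling that class's subclasses) and records the unit's output.  Stage
    two presents images of the focus class only and records all units.
    """
    data = generate_dataset(generator)
    model, _ = trained_model_on(data, training, master_seed, "s4")
    templates = data.subclass_templates
    if templates is None:
        raise ValueError("scenario 4 needs generator-produced subclass templates")
    K = generator.n_classes
    S = generator.n_subclasses_per_class
    shape = generator.image_shape

    def noisy_class_images(c: int, m: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        subs = np.arange(m) % S
        base = templates[c, subs]
        sd = generator.noise_sd * (
            1.0 + generator.noise_sd_jitter * rng.uniform(-1.0, 1.0, size=(m, 1, 1, 1))
        )
        imgs = np.clip(base + sd * rng.standard_normal((m, *shape)), 0, 1)
        return imgs, subs

    stage1 = np.empty((K, m_stage1))
    for c in range(K):
        imgs, _ = noisy_class_images(c, m_stage1, derive_seed(master_seed, f"s4/stage1/{c}"))
        out = activations(model, imgs, layer_id="output")
        stage1[c] = out.values[:, c]

    imgs, subs = noisy_class_images(focus_unit, m_stage2, derive_seed(master_seed, "s4/stage2"))
    out = activations(model, imgs, layer_id="output")
    stage2 = UnitActivityMatrix(X=out.values.T, trial_sublabels=subs)
    return UnitActivityMatrix(X=stage1), stage2


def run_scenario_4_grain(
    generator: GeneratorConfig | None = None,
    training: TrainingConfig | None = None,
    k: int = 9,
    m_stage1: int = 1000,
    m_stage2: int = 1000,
    alpha: float = 0.05,
    focus_unit: int = 5,
    master_seed: int = 0,
    return_matrices: bool = False,
) -> dict[str, Any]:
    """Coarse- vs fine-grained within-unit variance and the resulting
    noise-correlation estimates (reference sizes N=10, M=1000, k=9)."""
    generator = generator or GeneratorConfig(
        n_classes=10,
        n_subclasses_per_class=5,
        n_per_class=150,
        image_shape=(12, 12, 3),
        noise_sd=0.08,
        template_amplitude=0.2,
        global_weight=0.5,
        subclass_scale=1.0,
        seed=derive_seed(master_seed, "s4/data"),
    )
    training = training or TrainingConfig(epochs=120)
    stage1, stage2 = _scenario4_traces(
        generator, training, m_stage1, m_stage2, focus_unit, master_seed
    )
    sigma2 = estimate_within_unit_variability(stage1, k)
    results: dict[str, Any] = {
        "scenario": "s4_grain",
        "k": k,
        "n_units": stage1.n_units,
        "m_trials": m_stage2,
        "alpha": alpha,
        "focus_unit": focus_unit,
    }
    for grain in ("coarse", "fine"):
        model = make_population_model(stage2, sigma2, k, grain=grain, alpha=alpha)
        tensor = sample_neurons(model, seed=derive_seed(master_seed, f"s4/sample/{grain}"))
        summary = pairwise_noise_correlation(tensor, focus_unit=focus_unit)
        results[f"{grain}_avg_total"] = summary.avg_total
        results[f"{grain}_avg_within_unit"] = summary.avg_within_unit
        if return_matrices:
            results[f"{grain}_matrix"] = summary.matrix
    results["f_critical"] = make_population_model(
        stage2, sigma2, k, grain="fine", alpha=alpha
    ).f_crit
    return results


def run_scenario_4_rhythm(
    generator: GeneratorConfig | None = None,
    training: TrainingConfig | None = None,
    k: int = 9,
    m_stage1: int = 1000,
    m_stage2: int = 1000,
    alpha: float = 0.05,
    focus_unit: int = 5,
    master_seed: int = 0,
    return_matrices: bool = False,
) -> dict[str, Any]:
    """Control vs. globally-shared alternating rhythm at matched
    within-unit variability."""
    generator = generator or GeneratorConfig(
        n_classes=10,
        n_subclasses_per_class=5,
        n_per_class=150,
        image_shape=(12, 12, 3),
        noise_sd=0.08,
        template_amplitude=0.2,
        global_weight=0.5,
        subclass_scale=1.0,
        seed=derive_seed(master_seed, "s4/data"),
    )
    training = training or TrainingConfig(epochs=120)
    stage1, stage2 = _scenario4_traces(
        generator, training, m_stage1, m_stage2, focus_unit, master_seed
    )
    sigma2 = estimate_within_unit_variability(stage1, k)
    results: dict[str, Any] = {
        "scenario": "s4_rhythm",
        "k": k,
        "n_units": stage1.n_units,
        "m_trials": m_stage2,
        "focus_unit": focus_unit,
    }
    control = make_population_model(stage2, sigma2, k, grain="coarse", alpha=alpha)
    perturbed = apply_internal_rhythm(stage2, seed=derive_seed(master_seed, "s4/rhythm"))
    # within-unit variabilities identical to the control's
    rhythm_model = make_population_model(perturbed, sigma2, k, grain="coarse", alpha=alpha)
    for name, model in (("control", control), ("rhythm", rhythm_model)):
        tensor = sample_neurons(model, seed=derive_seed(master_seed, f"s4/sample/{name}"))
        summary = pairwise_noise_correlation(tensor, focus_unit=focus_unit)
        results[f"{name}_avg_total"] = summary.avg_total
        results[f"{name}_avg_within_unit"] = summary.avg_within_unit
        if return_matrices:
            results[f"{name}_matrix"] = summary.matrix
    return results


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunConfig:
    """Single-file description of an end-to-end run."""

    scenario: str = "all"
    master_seed: int = 0
    output_dir: str = "ncbl_out"
    generator: dict[str, Any] | None = None
    training: dict[str, Any] | None = None
    s1: dict[str, Any] = field(default_factory=dict)
    s2: dict[str, Any] = field(default_factory=dict)
    s3: dict[str, Any] = field(default_factory=dict)
    s4: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS + ("all",):
            raise ValueError(
                f"scenario must be one of {SCENARIOS + ('all',)}, got {self.scenario!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def generator_config(self, seed: int) -> GeneratorConfig | None:
        if self.generator is None:
            return None
        g = dict(self.generator)
        g.setdefault("seed", seed)
        if "image_shape" in g:
            g["image_shape"] = tuple(g["image_shape"])
        if "confusable_pairs" in g:
            g["confusable_pairs"] = tuple(tuple(p) for p in g["confusable_pairs"])
        return GeneratorConfig(**g)

    def training_config(self) -> TrainingConfig | None:
        if self.training is None:
            return None
        t = dict(self.training)
        if "hidden_sizes" in t:
            t["hidden_sizes"] = tuple(t["hidden_sizes"])
        return TrainingConfig(**t)


def _sanitize(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items() if not isinstance(v, np.ndarray)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def run_scenario(config: RunConfig) -> dict[str, Any]:
    """Execute the requested scenario(s) and write reports and figures.

    Returns the report dict; also writes ``report.json`` plus per-scenario
    CSV tables and PNG figures (each figure has a CSV twin holding its
    exact plotted numbers) under ``config.output_dir``.
    """
    from ncbl import reporting

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = SCENARIOS if config.scenario == "all" else (config.scenario,)
    training = config.training_config()
    config_echo = asdict(config)
    config_echo.pop("output_dir", None)  # environment detail, not configuration
    report: dict[str, Any] = {
        "config": _sanitize(config_echo),
        "version": __version__,
        "python": platform.python_version(),
        "scenarios": {},
    }
    for name in wanted:
        seed = derive_seed(config.master_seed, f"{name}/generator")
        gen = config.generator_config(seed)
        if name == "s1":
            res = run_scenario_1(gen, training, master_seed=config.master_seed, **config.s1)
            reporting.write_s1(res, out)
        elif name == "s2":
            res = run_scenario_2(gen, training, master_seed=config.master_seed, **config.s2)
            reporting.write_s2(res, out)
        elif name == "s3":
            res = run_scenario_3(gen, training, master_seed=config.master_seed, **config.s3)
            reporting.write_s3(res, out)
        elif name == "s4_grain":
            res = run_scenario_4_grain(
                gen, training, master_seed=config.master_seed,
                return_matrices=True, **config.s4,
            )
            reporting.write_s4(res, out, "s4_grain", ("coarse", "fine"))
        else:
            res = run_scenario_4_rhythm(
                gen, training, master_seed=config.master_seed,
                return_matrices=True, **config.s4,
            )
            reporting.write_s4(res, out, "s4_rhythm", ("control", "rhythm"))
        report["scenarios"][name] = _sanitize(res)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
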