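# Methods

This note documents the models, calibrations, and design choices behind the
package, in the order the pipeline uses them.

## Synthetic stimulus sets

Each class template is a low-frequency Gaussian random field: per-channel
white noise smoothed with a Gaussian kernel (σ = min(H, W)/6, wrap-around
boundaries), standardized, and mapped to pixel space as
`clip(0.5 + amplitude · field, 0, 1)`. A sample is the subclass template
plus i.i.d. Gaussian pixel noise, clipped to [0, 1]. All draws flow from one
integer seed through a single `numpy` generator; identical configs are
bit-identical.

Structural knobs, each emulating a statistical property of natural image
sets that the scenarios depend on:

| knob | default | emulates |
| --- | --- | --- |
| `template_amplitude` | 0.25 | overall class separability; small values give the mediocre-classifier regime the bias scenarios assume |
| `noise_sd`, `noise_sd_jitter` | 0.06, 0 | pixel noise; jitter varies per-image difficulty, as real images do |
| `confusable_pairs`, `shared_weight` | — | visually similar category pairs (cat/dog, truck/automobile analogs) |
| `global_weight` | 0 | structure shared by *all* classes — natural-image statistics |
| `class_groups`, `group_weight` | — | superclass blocks (animals vs. vehicles) |
| `n_subclasses_per_class`, `subclass_scale` | 1, 0.35 | within-class heterogeneity ("breeds"); with one subclass the subclass is the class template itself |

Logos are small patches alpha-blended at fixed anchors:
`pixel ← (1−opacity)·pixel + opacity·patch`. The reference transparency is
80%, i.e. opacity 0.2. The pipeline's default logos are *bright* patches
(values 0.7–1.0): the blend then shifts every footprint pixel in one
direction, so the trained logo-detector weights share a sign and the
mean-intensity saliency measure (below) can register them. Sign-mixed
patches are also learned by the network, but their receptive-field imprint
cancels under a mean.

Splits are stratified per class with largest-remainder rounding, so tag
counts per class sum exactly to the class size (75/8/17 by default).

## The in-silico brain

A rectified-linear multilayer perceptron with softmax read-out, trained by
mini-batch SGD on cross-entropy plus an L2 penalty (one global coefficient),
with inverted dropout (keep probability 0.8) on hidden layers during
training only. The reference architecture is input → 400/200/100/50/20 → K;
the miniature scenario runs use 48/24 or 64/32 hidden units on 12×12×3
images, which preserves every qualitative effect at seconds of training
time. The engine is written explicitly (no framework) because the
receptive-field reconstruction needs the raw per-layer weight matrices with
a known layout (`z_l = a_{l−1} W_l + b_l`, weights `(fan_in, fan_out)`).

Numerical choices: He-style seeded initialization (N(0, 2/fan_in), zero
biases); softmax computed with max-shift; cross-entropy clipped at 1e−12;
argmax ties break to the lowest class index; a non-finite loss raises
immediately with the offending epoch. The step size optionally decays
geometrically per epoch (`lr_decay`): plain fixed-rate SGD can diverge after
convergence on easy tasks and collapse into a dead-ReLU state, which the
decay prevents. Gradients are verified against central finite differences
to 1e−5 relative error in the test suite.

## Scenario 1 — selectivity from one-hot regression

The unit's activation is regressed on one-hot class indicators **without an
intercept**: with an intercept the design is rank-deficient, and without it
each coefficient is exactly the class-mean activation, matching the
selectivity-profile reading. Coefficient p-values are two-sided t-tests with
n − J residual degrees of freedom (no multiple-testing correction, matching
common practice). Per-feature explained variance is the drop-one
semi-partial (RSS_without_j − RSS_full)/TSS with the *uncentered* TSS — the
no-intercept convention — under which the per-feature values are
nonnegative and sum exactly to the model R². No formula for a single
feature's "explained variance" is canonical here; this is one defensible
definition, isolated behind `onehot_regression`. A constant (zero-variance)
response returns zero R², zero explained variance and p = 1 by convention,
keeping property tests total.

## Scenario 2 — receptive fields and confound saliency

A class unit's receptive field is the route-summed backprojection of its
one-hot output vector: `v ← W_l v` from the deepest layer to the input,
realized exactly by the transposed weight chain. "Inverting" the
rectified-linear activation is not well defined; the default rectifies the
backprojected vector after each hidden-layer backstep (a route-positivity
reading), and a pure-linear variant (`rectify=False`) is provided — it
equals the plain weight-matrix product and serves as an analytic oracle.
Whether rectifying at every layer or only once is the better reading is
genuinely open; both are available, and the scenario conclusions hold under
either. Biases are excluded: routes are weight products only.

Maps are min-max normalized over the whole map (not per channel), with the
bounds stored for invertibility; an all-equal map (untrained model) is
flagged degenerate. `region_saliency` is the mean normalized intensity
inside a footprint over the mean outside (+∞ when the outside is exactly
zero). At miniature scale this ratio is bounded in practice near ~1.5
because the normalized baseline sits mid-range; the scenario's claim is the
*paired* comparison — the logo-trained model's footprint saliency exceeds
the clean-trained model's at matched seeds — which is what the tests assert.

## Scenario 3 — decoding baselines

Features are the raw last-hidden-layer activations, unstandardized. The
decoder is a maximum-margin linear classifier (hinge loss, L2, strength
1/C; C = 1 by default) trained on a balanced positive-vs-rest set
(100 positives vs. 11 from each of the 9 other classes in the miniature
run; 900 vs. 9×100 at reference scale) and evaluated on held-out positives
only — this measures sensitivity, not balanced accuracy, mirroring the
"accuracy for the target-class test images" protocol. `compare_baselines`
reports each accuracy next to its own chance level (1/K vs. 1/2) and flags
the inversion where the decoder's raw accuracy exceeds the network's.

The miniature dataset for this scenario pairs all ten classes into five
confusable pairs (shared weight 0.93): the network saturates around 60–70%
overall — the capacity-limited regime the scenario assumes — while the
binary read-out of the positive class scores near 1.0.

## Scenario 4 — noise-correlation estimation

Stage one presents each unit 1000 fresh noisy images of its own tuned class
(cycling that class's subclasses uniformly — how many stage-one trials use
which subclass is unspecified in the original design, and uniform cycling
is the neutral choice) and records the unit's output; the within-unit
variance is σ̂²_n = k·SD² with the sample SD (ddof 1) across those trials.
The per-trial notation σ̂²_{n,m} is read as constant across trials within a
unit: a per-trial SD of a single scalar is undefined. Stage two presents
1000 focus-class images and records all units, giving μ̂. Neurons are drawn
x ~ N_k(μ̂·1, σ̂²I), stacked unit-by-unit, and summarized by the pairwise
Pearson matrix across trials (exactly symmetrized; zero-variance neurons
get zero correlations with a warning).

The within-unit averages have a structural core: when stage-one and
stage-two trace variances match, the coarse estimate is var(μ̂)/(var(μ̂)+σ̂²)
≈ 1/(1+k) ≈ 0.10 and the fine estimate ≈ 1/(1+k/F) ≈ 0.28 — the pipeline
reproduces these at essentially any seed. The *total* average ordering
(fine > coarse) is a small effect and structurally delicate: softmax
outputs are zero-sum in covariance, so an exchangeable configuration has
mean cross-unit correlation ≈ −1/(N−1), which the fine model amplifies
downward; the ordering requires genuinely positive cross-unit signal
correlation. The default study conditions (shared global structure,
heterogeneous subclasses, moderate saturation) produce it at the reference
seed and at most seeds, but not universally — a limitation documented here
rather than hidden.

The internal rhythm adds one scalar r_m ~ U(0,1) per trial to every unit
(+ on odd-numbered trials, 1-based; − on even), following the
perturb-unit-traces reading; the rhythm model's within-unit variances are
set identical to the control's. An independent-per-unit rhythm variant
exists behind `shared=False`. At miniature scale the rhythm variance (1/3)
dwarfs the unit-trace variance, so the rhythm model's total average
saturates near 1.0 rather than the reference-scale ~0.2; the scenario's
claim is the ordering, which is robust.

## Orchestration and reproducibility

Every scenario draws its randomness from named sub-seeds
(SHA-256 of `"{master_seed}:{name}"`, truncated below 2³¹), so adding a
scenario never shifts another's stream, and a config + master seed
reproduces every CSV byte-identically (tested by hashing). Each figure has
a CSV twin holding exactly the plotted numbers; `ncbl report` re-renders
figures from CSVs alone. File output uses period decimals and fixed column
order regardless of locale.

## What the synthetic data does and does not show

The generator reproduces the *structural* premises (class templates,
confusable pairs, subclass heterogeneity, shared global statistics,
injectable confounds, variable difficulty) but not natural-image content:
textures, objects, or any feature a convolutional prior would exploit.
Passing tests therefore demonstrate that the four biases follow from the
analysis assumptions themselves — they arise even in a fully controlled
linear-algebraic world — not that the package's numbers match any
particular dataset's magnitudes. Magnitudes here are dataset-dependent by
design; orderings and calibrations (the 5% F-criterion rate, the
1/(1+k)-style within-unit ratios, the chance-level bookkeeping) are the
reproducible content. An optional CIFAR-10 batch reader is included for
full-scale reproduction when the archive is available locally; it is never
exercised by the tests.
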