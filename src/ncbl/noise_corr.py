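"""Stochastic per-neuron sampling from unit activity and noise correlation.

A trained network's units are deterministic: the same image always evokes
the same activation.  Real recordings are not — each "unit" stands for a
homogeneous population of k neurons whose within-trial sample mean is the
unit activity.  This module inverts that relationship: from observed unit
traces it calibrates a per-neuron normal model and draws synthetic neurons,
so that pairwise "noise" correlations can be estimated the way an
experimenter would.

Model: the k neurons of unit n in trial m are drawn
``x_{n,m} ~ N_k(mu_hat_{n,m} * 1, sigma2_hat_n * I)`` with
``mu_hat_{n,m} = X_{n,m}`` (the observed unit activity) and, under the
coarse-grained assumption, ``sigma2_hat_n = k * SD(X_{n,.})^2`` — which
makes the observed across-trial SD of the unit trace equal to the standard
error of the mean of k neurons.  The fine-grained assumption divides that
variance by the upper critical value of F(k-1, k-1), so that coarse and
fine within-unit variances differ by a just-significant variance ratio.

A global "internal rhythm" perturbation adds a shared uniform scalar to all
units' outputs on odd-numbered trials and subtracts it on even-numbered
ones, mimicking an unmeasured brain-state feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "UnitActivityMatrix",
    "PopulationModel",
    "NeuronSampleTensor",
    "CorrelationSummary",
    "estimate_within_unit_variability",
    "f_critical",
    "make_population_model",
    "sample_neurons",
    "apply_internal_rhythm",
    "pairwise_noise_correlation",
]

Grain = Literal["coarse", "fine"]


@dataclass
class UnitActivityMatrix:
    """N units x M trials of deterministic unit activity."""

    X: np.ndarray
    trial_sublabels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be N units x M trials")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("unit activity must be finite")
        if self.X.shape[0] < 1 or self.X.shape[1] < 2:
            raise ValueError("need N >= 1 units and M >= 2 trials")
        if self.trial_sublabels is not None:
            self.trial_sublabels = np.asarray(self.trial_sublabels, dtype=int)
            if self.trial_sublabels.shape[0] != self.X.shape[1]:
                raise ValueError("trial_sublabels length mismatch")

    @property
    def n_units(self) -> int:
        return self.X.shape[0]

    @property
    def n_trials(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PopulationModel:
    """Calibrated per-neuron sampling model for N units over M trials."""

    mu_hat: np.ndarray          # (N, M) per-unit per-trial neuron mean
    sigma2_hat: np.ndarray      # (N,) within-unit variance
    k: int                      # neurons per unit
    grain: Grain
    alpha: float
    f_crit: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_hat", np.asarray(self.mu_hat, dtype=float))
        object.__setattr__(self, "sigma2_hat", np.asarray(self.sigma2_hat, dtype=float))
        if self.mu_hat.ndim != 2:
            raise ValueError("mu_hat must be N x M")
        if self.sigma2_hat.shape != (self.mu_hat.shape[0],):
            raise ValueError("sigma2_hat must have one entry per unit")
        if (self.sigma2_hat < 0).any():
            raise ValueError("within-unit variance must be nonnegative")
        if self.k < 2:
            raise ValueError("need k >= 2 neurons per unit")

    @property
    def n_units(self) -> int:
        return self.mu_hat.shape[0]

    @property
    def n_trials(self) -> int:
        return self.mu_hat.shape[1]


@dataclass(frozen=True)
class NeuronSampleTensor:
    """(N*k) sampled neurons x M trials, with each neuron's parent unit."""

    samples: np.ndarray
    unit_of_neuron: np.ndarray
    k: int
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.samples.shape[0]

    @property
    def n_trials(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class CorrelationSummary:
    """Pairwise Pearson matrix over sampled neurons with its averages."""

    matrix: np.ndarray
    avg_total: float
    avg_within_unit: float
    focus_unit: int


def estimate_within_unit_variability(
    stage1_traces: UnitActivityMatrix, k: int
) -> np.ndarray:
    """Per-unit within-unit variance: ``sigma2_n = k * SD(X_n,.)^2``.

    The SD is the sample standard deviation (ddof 1) across the stage-one
    trials, so the unit trace's SD becomes the standard error of the mean
    of k neurons.
    """
    if k < 2:
        raise ValueError("need k >= 2 neurons per unit")
    return k * np.var(stage1_traces.X, axis=1, ddof=1)


def f_critical(alpha: float, k: int) -> float:
    """Upper-alpha critical value of the F distribution with (k-1, k-1) df."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 2:
        raise ValueError("need k >= 2 (df = k - 1 >= 1)")
    return float(stats.f.ppf(1.0 - alpha, k - 1, k - 1))


def make_population_model(
    stage2_traces: UnitActivityMatrix,
    sigma2: np.ndarray,
    k: int,
    grain: Grain = "coarse",
    alpha: float = 0.05,
) -> PopulationModel:
    """Calibrate the per-neuron model on observed unit traces.

    ``mu_hat`` expands each unit activity by the all-ones vector over k
    neurons; the coarse grain keeps ``sigma2`` as given while the fine grain
    divides it by the F critical value, making the coarse/fine variance
    ratio exactly the borderline-significant one.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.shape != (stage2_traces.n_units,):
        raise ValueError("sigma2 must have one entry per unit")
    if (sigma2 < 0).any():
        raise ValueError("within-unit variance must be nonnegative")
    if grain not in ("coarse", "fine"):
        raise ValueError(f"unknown grain {grain!r}")
    fc = f_critical(alpha, k)
    sigma2_model = sigma2 / fc if grain == "fine" else sigma2.copy()
    return PopulationModel(
        mu_hat=stage2_traces.X.copy(),
        sigma2_hat=sigma2_model,
        k=k,
        grain=grain,
        alpha=alpha,
        f_crit=fc,
    )


def sample_neurons(model: PopulationModel, seed: int) -> NeuronSampleTensor:
    """Draw ``x_{n,m} ~ N_k(mu_hat_{n,m} 1, sigma2_hat_n I)`` for all n, m.

    Neurons are stacked unit-by-unit: rows ``n*k .. n*k+k-1`` belong to
    unit n.  Identical seed gives a bit-identical tensor.
    """
    rng = np.random.default_rng(seed)
    N, M, k = model.n_units, model.n_trials, model.k
    noise = rng.standard_normal((N, k, M))
    samples = model.mu_hat[:, None, :] + np.sqrt(model.sigma2_hat)[:, None, None] * noise
    return NeuronSampleTensor(
        samples=samples.reshape(N * k, M),
        unit_of_neuron=np.repeat(np.arange(N), k),
        k=k,
        seed=seed,
    )


def apply_internal_rhythm(
    traces: UnitActivityMatrix,
    seed: int,
    rhythm: np.ndarray | None = None,
    shared: bool = True,
) -> UnitActivityMatrix:
    """Superimpose a global alternating brain-state rhythm on unit traces.

    One scalar ``r_m ~ U(0, 1)`` per trial is added to every unit's output
    on odd-numbered trials (1-based) and subtracted on even-numbered ones.
    ``rhythm`` overrides the draw with explicit per-trial values; with
    ``shared=False`` each unit gets an independent rhythm instead of the
    global one.
    """
    rng = np.random.default_rng(seed)
    N, M = traces.n_units, traces.n_trials
    if rhythm is not None:
        r = np.asarray(rhythm, dtype=float)
        if r.shape not in ((M,), (N, M)):
            raise ValueError("explicit rhythm must have shape (M,) or (N, M)")
    elif shared:
        r = rng.uniform(0.0, 1.0, size=M)
    else:
        r = rng.uniform(0.0, 1.0, size=(N, M))
    sign = np.where(np.arange(M) % 2 == 0, 1.0, -1.0)  # trial 1 (index 0) is odd
    X = traces.X + sign * r  # broadcasts over units for a shared rhythm
    return UnitActivityMatrix(X=X, trial_sublabels=traces.trial_sublabels)


def pairwise_noise_correlation(
    samples: NeuronSampleTensor, focus_unit: int = 0
) -> CorrelationSummary:
    """Pearson correlation across trials for every sampled-neuron pair.

    ``avg_total`` averages the strict upper triangle over all neurons;
    ``avg_within_unit`` restricts it to the focus unit's k neurons.  A
    zero-variance neuron's correlations are defined as 0 (with a warning)
    so the summary stays total.
    """
    if samples.n_trials < 3:
        raise ValueError("need M >= 3 trials for a correlation estimate")
    if focus_unit not in set(samples.unit_of_neuron.tolist()):
        raise ValueError(f"focus unit {focus_unit} has no sampled neurons")
    x = samples.samples
    sd = x.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance neuron trace(s); their "
            "correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    corr = (corr + corr.T) / 2.0  # exact symmetry despite rounding
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)

    iu = np.triu_indices(samples.n_neurons, k=1)
    avg_total = float(corr[iu].mean())
    members = np.flatnonzero(samples.unit_of_neuron == focus_unit)
    sub = corr[np.ix_(members, members)]
    iu_sub = np.triu_indices(len(members), k=1)
    avg_within = float(sub[iu_sub].mean())
    return CorrelationSummary(
        matrix=corr,
        avg_total=avg_total,
        avg_within_unit=avg_within,
        focus_unit=int(focus_unit),
    )
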