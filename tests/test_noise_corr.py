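"""Population-model calibration, neuron sampling, and correlation summaries."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from ncbl.noise_corr import (
    NeuronSampleTensor,
    UnitActivityMatrix,
    apply_internal_rhythm,
    estimate_within_unit_variability,
    f_critical,
    make_population_model,
    pairwise_noise_correlation,
    sample_neurons,
)


class TestWithinUnitVariability:
    def test_constant_trace_zero(self):
        traces = UnitActivityMatrix(X=np.full((2, 5), 0.4))
        assert np.all(estimate_within_unit_variability(traces, 9) == 0.0)

    def test_hand_computed_binary_trace(self):
        """Trace {0,1}: sample variance 0.5, times k=9 gives 4.5."""
        traces = UnitActivityMatrix(X=np.array([[0.0, 1.0]]))
        sigma2 = estimate_within_unit_variability(traces, 9)
        assert sigma2[0] == pytest.approx(4.5)

    def test_scaling_homogeneity(self, rng):
        X = rng.random((3, 20))
        base = estimate_within_unit_variability(UnitActivityMatrix(X=X), 5)
        scaled = estimate_within_unit_variability(UnitActivityMatrix(X=3.0 * X), 5)
        assert np.allclose(scaled, 9.0 * base)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            UnitActivityMatrix(X=np.ones((2, 1)))


class TestFCritical:
    def test_median_symmetry(self):
        """F(d, d) has median exactly 1, so the 50% critical value is 1."""
        for k in (2, 5, 9, 30):
            assert f_critical(0.5, k) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("alpha,k", [(0.05, 9), (0.05, 2), (0.01, 9), (0.1, 5)])
    def test_matches_cdf_inversion_oracle(self, alpha, k):
        """Independent root-finding inversion of the F CDF."""
        target = 1.0 - alpha
        oracle = brentq(lambda x: stats.f.cdf(x, k - 1, k - 1) - target, 1e-9, 1e9,
                        xtol=1e-10, rtol=1e-12)
        assert f_critical(alpha, k) == pytest.approx(oracle, rel=1e-8)

    def test_reference_values(self):
        assert f_critical(0.05, 9) == pytest.approx(3.438, abs=2e-3)
        assert f_critical(0.05, 2) == pytest.approx(161.45, abs=0.01)

    def test_monotone_decreasing_in_k(self):
        values = [f_critical(0.05, k) for k in range(2, 31)]
        assert all(b < a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("alpha,k", [(0.0, 9), (1.0, 9), (0.05, 1)])
    def test_invalid_arguments_rejected(self, alpha, k):
        with pytest.raises(ValueError):
            f_critical(alpha, k)


class TestMakePopulationModel:
    def make_traces(self, rng, n=3, m=20):
        return UnitActivityMatrix(X=rng.random((n, m)))

    def test_fine_coarse_ratio_is_exactly_one_over_f(self, rng):
        traces = self.make_traces(rng)
        sigma2 = estimate_within_unit_variability(traces, 9)
        coarse = make_population_model(traces, sigma2, 9, grain="coarse")
        fine = make_population_model(traces, sigma2, 9, grain="fine")
        assert np.array_equal(fine.sigma2_hat, coarse.sigma2_hat / fine.f_crit)

    def test_hand_computed_fine_variance(self, rng):
        """4.5 / F(0.05; 8, 8) is about 1.309."""
        traces = self.make_traces(rng, n=1)
        fine = make_population_model(traces, np.array([4.5]), 9, grain="fine",
                                     alpha=0.05)
        assert fine.sigma2_hat[0] == pytest.approx(4.5 / 3.438101, rel=1e-5)
        assert fine.sigma2_hat[0] == pytest.approx(1.309, abs=2e-3)

    def test_mu_hat_is_observed_unit_activity(self, rng):
        traces = self.make_traces(rng)
        model = make_population_model(traces, np.zeros(3), 9)
        assert np.array_equal(model.mu_hat, traces.X)

    def test_negative_variance_rejected(self, rng):
        traces = self.make_traces(rng)
        with pytest.raises(ValueError):
            make_population_model(traces, np.array([1.0, -0.1, 0.2]), 9)

    def test_unknown_grain_rejected(self, rng):
        traces = self.make_traces(rng)
        with pytest.raises(ValueError, match="grain"):
            make_population_model(traces, np.zeros(3), 9, grain="medium")


class TestSampleNeurons:
    def test_zero_variance_copies_unit_trace(self, rng):
        traces = UnitActivityMatrix(X=rng.random((2, 6)))
        model = make_population_model(traces, np.zeros(2), 4)
        tensor = sample_neurons(model, seed=0)
        assert tensor.samples.shape == (8, 6)
        for n in range(2):
            for j in range(4):
                assert np.array_equal(tensor.samples[n * 4 + j], traces.X[n])

    def test_same_seed_bit_identical(self, rng):
        traces = UnitActivityMatrix(X=rng.random((3, 10)))
        model = make_population_model(traces, np.full(3, 0.5), 5)
        a, b = sample_neurons(model, seed=42), sample_neurons(model, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_cell_variance_recovers_sigma2(self, rng):
        """Across many redraws, per-cell sample variance approaches sigma2."""
        traces = UnitActivityMatrix(X=np.zeros((1, 2)) + 0.3)
        model = make_population_model(traces, np.array([0.8]), 2000)
        tensor = sample_neurons(model, seed=7)
        var = tensor.samples[:, 0].var(ddof=1)
        se = 0.8 * np.sqrt(2.0 / (2000 - 1))  # SE of a normal sample variance
        assert abs(var - 0.8) < 4 * se


class TestInternalRhythm:
    def test_zero_rhythm_unchanged(self, rng):
        traces = UnitActivityMatrix(X=rng.random((3, 6)))
        out = apply_internal_rhythm(traces, seed=0, rhythm=np.zeros(6))
        assert np.array_equal(out.X, traces.X)

    def test_forced_half_shift_alternates_sign(self):
        """r = (0.5, 0.5): trial 1 gains +0.5, trial 2 loses 0.5, every unit."""
        traces = UnitActivityMatrix(X=np.zeros((3, 2)))
        out = apply_internal_rhythm(traces, seed=0, rhythm=np.array([0.5, 0.5]))
        assert np.allclose(out.X[:, 0], 0.5)
        assert np.allclose(out.X[:, 1], -0.5)

    def test_shared_rhythm_identical_across_units(self):
        traces = UnitActivityMatrix(X=np.zeros((4, 10)))
        out = apply_internal_rhythm(traces, seed=3, shared=True)
        # after sign removal every unit carries the same per-trial scalar
        assert np.allclose(out.X, out.X[0])

    def test_independent_rhythm_differs_across_units(self):
        traces = UnitActivityMatrix(X=np.zeros((4, 10)))
        out = apply_internal_rhythm(traces, seed=3, shared=False)
        assert not np.allclose(out.X[0], out.X[1])

    def test_bad_rhythm_shape_rejected(self):
        traces = UnitActivityMatrix(X=np.zeros((2, 4)))
        with pytest.raises(ValueError, match="shape"):
            apply_internal_rhythm(traces, seed=0, rhythm=np.zeros(3))


class TestPairwiseNoiseCorrelation:
    def tensor_from(self, samples, k):
        samples = np.asarray(samples, dtype=float)
        n_units = samples.shape[0] // k
        return NeuronSampleTensor(samples=samples,
                                  unit_of_neuron=np.repeat(np.arange(n_units), k),
                                  k=k, seed=0)

    def test_identical_traces_correlate_perfectly(self):
        trace = np.array([0.1, 0.5, 0.2, 0.9])
        tensor = self.tensor_from(np.vstack([trace, trace]), k=2)
        summary = pairwise_noise_correlation(tensor, focus_unit=0)
        assert summary.matrix[0, 1] == pytest.approx(1.0)
        assert summary.avg_total == pytest.approx(1.0)

    def test_matches_textbook_covariance_oracle(self, rng):
        """3 neurons x 4 trials against the direct covariance formula."""
        x = rng.random((3, 4))
        tensor = self.tensor_from(x, k=3)
        summary = pairwise_noise_correlation(tensor, focus_unit=0)
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                rho = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert summary.matrix[i, j] == pytest.approx(rho, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self, rng):
        x = rng.random((6, 12))
        summary = pairwise_noise_correlation(self.tensor_from(x, k=3), 1)
        assert np.array_equal(summary.matrix, summary.matrix.T)
        assert np.all(np.diag(summary.matrix) == 1.0)
        assert summary.matrix.min() >= -1.0 and summary.matrix.max() <= 1.0

    def test_zero_variance_neuron_warns_and_zeroes(self, rng):
        x = rng.random((4, 8))
        x[2] = 0.5
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            summary = pairwise_noise_correlation(self.tensor_from(x, k=2), 0)
        assert np.all(summary.matrix[2, [0, 1, 3]] == 0.0)
        assert summary.matrix[2, 2] == 1.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="M >= 3"):
            pairwise_noise_correlation(self.tensor_from(np.zeros((2, 2)), k=2), 0)

    def test_pure_noise_avg_total_vanishes_with_trials(self):
        """Identical stimuli, independent sampling: correlations decay as
        1/sqrt(M)."""
        M = 4000
        traces = UnitActivityMatrix(X=np.full((4, M), 0.5))
        model = make_population_model(traces, np.full(4, 0.3), 3)
        tensor = sample_neurons(model, seed=11)
        summary = pairwise_noise_correlation(tensor, 0)
        assert abs(summary.avg_total) < 3.0 / np.sqrt(M)
        assert abs(summary.avg_within_unit) < 3.0 / np.sqrt(M)


class TestGrainAndRhythmOrdering:
    """Model-free checks of the two scenario orderings on synthetic traces."""

    def subclass_traces(self, rng, n_units=6, m=400):
        # per-trial unit means with real across-trial (subclass) spread
        base = rng.random((n_units, 1))
        spread = 0.2 * rng.standard_normal((n_units, m))
        return UnitActivityMatrix(X=base + spread)

    def test_fine_grain_raises_within_unit_correlation(self, rng):
        traces = self.subclass_traces(rng)
        sigma2 = estimate_within_unit_variability(traces, 9)
        summaries = {}
        for grain in ("coarse", "fine"):
            model = make_population_model(traces, sigma2, 9, grain=grain)
            tensor = sample_neurons(model, seed=5)
            summaries[grain] = pairwise_noise_correlation(tensor, 0)
        assert summaries["fine"].avg_within_unit > summaries["coarse"].avg_within_unit

    def test_rhythm_raises_total_correlation_at_matched_variability(self, rng):
        traces = self.subclass_traces(rng)
        sigma2 = estimate_within_unit_variability(traces, 9)
        control = make_population_model(traces, sigma2, 9, grain="coarse")
        perturbed = apply_internal_rhythm(traces, seed=8)
        rhythm = make_population_model(perturbed, sigma2, 9, grain="coarse")
        s_control = pairwise_noise_correlation(sample_neurons(control, seed=6), 0)
        s_rhythm = pairwise_noise_correlation(sample_neurons(rhythm, seed=6), 0)
        assert s_rhythm.avg_total > s_control.avg_total
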