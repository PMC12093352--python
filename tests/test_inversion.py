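import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldcm.exceptions import DataError, DesignError, LdcmError
from ldcm.forward import FrequencyGrid, CrossSpectrum
from ldcm.inversion import (
    vectorize_csd,
    devectorize_csd,
    variational_laplace,
    fit_dcm,
    FitOptions,
)
from ldcm.longitudinal import ones_design, apply_condition_effects
from ldcm.model import PriorDensity, get_layout
from ldcm.synthetic import simulate_csd
from ldcm.forward import predict_csd


def _random_hermitian(rng, F, R):
    A = rng.standard_normal((F, R, R)) + 1j * rng.standard_normal((F, R, R))
    S = A @ np.conj(np.swapaxes(A, -1, -2)) / R
    return S


class TestVectorisation:
    def test_vector_length_two_regions(self):
        rng = np.random.default_rng(0)
        F, R = 7, 2
        grid = FrequencyGrid(np.arange(1.0, F + 1.0))
        csd = CrossSpectrum(grid, _random_hermitian(rng, F, R), ("x", "y"))
        y, masks = vectorize_csd(csd)
        assert y.size == F * 4          # 3 real + 1 imaginary per frequency
        assert masks[0].sum() == F * R  # auto-spectral entries

    @settings(deadline=None, max_examples=20)
    @given(st.integers(1, 5), st.integers(1, 4), st.integers(0, 1000))
    def test_round_trip(self, F, R, seed):
        rng = np.random.default_rng(seed)
        grid = FrequencyGrid(np.arange(1.0, F + 1.0))
        labels = tuple(f"r{i}" for i in range(R))
        S = _random_hermitian(rng, F, R)
        csd = CrossSpectrum(grid, S, labels)
        y, _ = vectorize_csd(csd)
        back = devectorize_csd(y, grid, labels)
        assert np.allclose(back.S, S)

    def test_real_diagonal_preserved_exactly(self):
        rng = np.random.default_rng(1)
        grid = FrequencyGrid(np.arange(1.0, 4.0))
        S = _random_hermitian(rng, 3, 3)
        csd = CrossSpectrum(grid, S, ("a", "b", "c"))
        y, _ = vectorize_csd(csd)
        back = devectorize_csd(y, grid, ("a", "b", "c"))
        assert np.array_equal(np.einsum("frr->fr", back.S).real,
                              np.einsum("frr->fr", S).real)

    def test_non_hermitian_rejected(self):
        grid = FrequencyGrid(np.arange(1.0, 3.0))
        S = np.zeros((2, 2, 2), dtype=complex)
        S[:, 0, 1] = 1.0
        S[:, 1, 0] = 5.0
        with pytest.raises(DataError):
            vectorize_csd(CrossSpectrum(grid, S, ("a", "b")))


class TestVariationalLaplace:
    def _linear_problem(self, seed=0, n=5, ny=40, prec=50.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((ny, n))
        theta = rng.standard_normal(n)
        y = X @ theta + rng.standard_normal(ny) / np.sqrt(prec)
        prior = PriorDensity(np.zeros(n), np.eye(n) * 2.0)
        return X, y, prior, prec

    def test_conjugate_linear_gaussian_match(self):
        X, y, prior, prec = self._linear_problem()
        opts = FitOptions(hyper_mean=np.log(prec), hyper_variance=1e-10,
                          tolerance=1e-8)
        post = variational_laplace(lambda th: th @ X.T, y, prior, opts)
        P = X.T @ X * prec + np.linalg.inv(prior.covariance)
        C = np.linalg.inv(P)
        m = C @ (X.T @ y * prec)
        assert np.abs(post.mean - m).max() < 1e-6
        assert np.abs(post.covariance - C).max() < 1e-6

    def test_free_energy_equals_analytic_log_evidence(self):
        from scipy.stats import multivariate_normal
        X, y, prior, prec = self._linear_problem(seed=3)
        opts = FitOptions(hyper_mean=np.log(prec), hyper_variance=1e-10,
                          tolerance=1e-8)
        post = variational_laplace(lambda th: th @ X.T, y, prior, opts)
        Sy = X @ prior.covariance @ X.T + np.eye(y.size) / prec
        logev = multivariate_normal.logpdf(y, np.zeros(y.size), Sy)
        assert abs(post.free_energy - logev) < 1e-4

    def test_monotone_free_energy_trace(self):
        X, y, prior, _ = self._linear_problem(seed=5)
        post = variational_laplace(lambda th: th @ X.T, y, prior, FitOptions())
        trace = post.diagnostics["f_trace"]
        assert np.all(np.diff(trace) >= -1e-9)

    def test_flat_likelihood_returns_prior(self):
        prior = PriorDensity(np.array([0.3, -0.2]), np.diag([0.5, 1.5]))
        y = np.array([1.0, 2.0, 3.0])
        const = np.array([1.0, 2.0, 3.0])
        post = variational_laplace(
            lambda th: np.tile(const, (th.shape[0], 1)), y, prior, FitOptions())
        assert np.allclose(post.mean, prior.mean, atol=1e-8)
        assert np.allclose(post.covariance, prior.covariance, rtol=1e-6)
        # zero complexity: F is pure accuracy, and KL(q||p) vanishes
        d = post.mean - prior.mean
        kl = 0.5 * d @ np.linalg.solve(prior.covariance, d)
        assert kl < 1e-12

    def test_posterior_covariance_psd(self):
        X, y, prior, _ = self._linear_problem(seed=7)
        post = variational_laplace(lambda th: th @ X.T, y, prior, FitOptions())
        assert np.linalg.eigvalsh(post.covariance).min() >= -1e-10

    def test_nonfinite_initial_prediction_raises(self):
        prior = PriorDensity(np.zeros(2), np.eye(2))
        bad = lambda th: np.full((th.shape[0], 3), np.nan)
        with pytest.raises(LdcmError):
            variational_laplace(bad, np.zeros(3), prior, FitOptions())


class TestFitDcm:
    def test_self_consistency_at_prior_mean(self, variant2, coarse_grid):
        from ldcm.model import ParameterVector
        theta0 = ParameterVector.default(variant2)
        feat = simulate_csd(theta0, variant2, coarse_grid,
                            n_effective_trials=100000, seed=0)
        post = fit_dcm(feat, variant2, options=FitOptions(seed=0))
        prior_sd = np.sqrt(np.diag(post.prior.covariance))
        z = np.abs(post.mean - post.prior.mean) / prior_sd
        assert np.median(z) < 0.2

    def test_single_condition_has_no_condition_effects(self, variant2,
                                                       stable_theta2, coarse_grid):
        feat = simulate_csd(stable_theta2, variant2, coarse_grid, seed=1)
        post = fit_dcm(feat, variant2, options=FitOptions(max_iterations=2))
        assert post.n == get_layout(variant2).n_params
        assert post.B_mean.size == 0

    def test_two_conditions_require_design(self, variant2, stable_theta2,
                                           coarse_grid):
        feat = simulate_csd(stable_theta2, variant2, coarse_grid, seed=1)
        with pytest.raises(DesignError):
            fit_dcm((feat, feat), variant2, design=None)

    def test_identical_conditions_give_null_condition_effects(
            self, variant2, stable_theta2, coarse_grid):
        design = ones_design(variant2)
        bl = simulate_csd(stable_theta2, variant2, coarse_grid,
                          n_effective_trials=400, seed=2)
        af = simulate_csd(stable_theta2, variant2, coarse_grid,
                          n_effective_trials=400, seed=3)
        post = fit_dcm((bl, af), variant2, design,
                       options=FitOptions(max_iterations=48, seed=0))
        B = post.B_mean
        B_sd = np.sqrt(np.diag(post.covariance)[post.n_theta:])
        assert np.all(np.abs(B) < 2.0 * B_sd)

    def test_known_condition_effect_recovers_sign(self, variant2, stable_theta2,
                                                  coarse_grid):
        layout = get_layout(variant2)
        design = ones_design(variant2)
        gi = layout.h_positions.index((1, 1))   # SP self-gain of region 0
        effect = 0.3 * np.sqrt(FitOptions().b_prior_variance)
        hits = 0
        n_rep = 5
        for rep in range(n_rep):
            B = np.zeros(design.n_groups)
            B[gi] = effect
            th_af = apply_condition_effects(stable_theta2, design, B)
            bl = simulate_csd(stable_theta2, variant2, coarse_grid, 250,
                              seed=100 + rep)
            af = simulate_csd(th_af, variant2, coarse_grid, 250, seed=200 + rep)
            post = fit_dcm((bl, af), variant2, design,
                           options=FitOptions(max_iterations=48, seed=0))
            hits += post.B_mean[gi] > 0
        assert hits >= n_rep - 1

    def test_monotone_f_trace_in_dcm_fit(self, variant2, stable_theta2,
                                         coarse_grid):
        feat = simulate_csd(stable_theta2, variant2, coarse_grid, seed=5)
        post = fit_dcm(feat, variant2, options=FitOptions(max_iterations=24,
                                                          seed=0))
        trace = post.diagnostics["f_trace"]
        assert np.all(np.diff(trace) >= -1e-9)
        assert np.linalg.eigvalsh(post.covariance).min() >= -1e-10
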