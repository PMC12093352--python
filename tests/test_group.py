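import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldcm.exceptions import DataError, DesignError
from ldcm.group import (
    GroupDesign,
    ModelEvidenceTable,
    bayesian_model_reduction,
    reduce_parameters,
    fixed_effects_bms,
    peb_fit,
    bma,
    zscore_regressor,
)
from ldcm.inversion import Posterior, variational_laplace, FitOptions
from ldcm.model import PriorDensity


def _linear_posterior(seed=0, n=4, ny=30, prec=20.0, theta=None,
                      prior_cov=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((ny, n))
    theta = rng.standard_normal(n) if theta is None else np.asarray(theta)
    y = X @ theta + rng.standard_normal(ny) / np.sqrt(prec)
    prior = PriorDensity(np.zeros(n), prior_cov if prior_cov is not None
                         else np.eye(n))
    opts = FitOptions(hyper_mean=np.log(prec), hyper_variance=1e-10,
                      tolerance=1e-8)
    post = variational_laplace(lambda th: th @ X.T, y, prior, opts)
    return post, X, y, prior, prec


class TestBmr:
    def test_identical_priors_no_change(self):
        post, _, _, prior, _ = _linear_posterior()
        red, dF = bayesian_model_reduction(post, prior, prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(red.mean, post.mean)
        assert np.allclose(red.covariance, post.covariance)

    def test_matches_direct_evidence_on_conjugate_toy(self):
        from scipy.stats import multivariate_normal
        post, X, y, prior, prec = _linear_posterior(seed=2)
        reduced = reduce_parameters(prior, [2, 3], variance=1e-6)
        _, dF = bayesian_model_reduction(post, prior, reduced)

        def logev(C0):
            Sy = X @ C0 @ X.T + np.eye(y.size) / prec
            return multivariate_normal.logpdf(y, np.zeros(y.size), Sy)
        direct = logev(reduced.covariance) - logev(prior.covariance)
        assert abs(dF - direct) < 1e-6

    def test_removing_uninformed_parameter_saves_complexity(self):
        # a redundant parameter that only fits noise: removing it raises evidence
        rng = np.random.default_rng(3)
        ny, n = 30, 3
        X = np.column_stack([rng.standard_normal((ny, 2)),
                             0.3 * rng.standard_normal(ny)])
        prec = 30.0
        y = X[:, :2] @ np.array([1.0, -1.0]) + rng.standard_normal(ny) / np.sqrt(prec)
        prior = PriorDensity(np.zeros(n), np.eye(n))
        opts = FitOptions(hyper_mean=np.log(prec), hyper_variance=1e-10,
                          tolerance=1e-8)
        post = variational_laplace(lambda th: th @ X.T, y, prior, opts)
        reduced = reduce_parameters(prior, [2], variance=1e-8)
        _, dF = bayesian_model_reduction(post, prior, reduced)
        assert dF > 0

    def test_rejects_non_psd_inputs(self):
        post, _, _, prior, _ = _linear_posterior()
        bad = PriorDensity(prior.mean, prior.covariance.copy())
        bad.covariance[0, 0] = -1.0
        with pytest.raises(DataError):
            bayesian_model_reduction(post, bad, prior)


class TestExhaustiveSearch:
    def test_recovers_supported_groups(self):
        from ldcm.group import exhaustive_bmr_search
        from ldcm.longitudinal import ConditionDesign, ConditionGroup

        # posterior over 3 condition effects: two informed, one at prior
        rng = np.random.default_rng(0)
        ny, n = 60, 3
        X = np.column_stack([rng.standard_normal((ny, 2)),
                             0.1 * rng.standard_normal(ny)])
        prec = 50.0
        y = X[:, :2] @ np.array([1.0, -0.8]) + rng.standard_normal(ny) / np.sqrt(prec)
        prior = PriorDensity(np.zeros(n), np.eye(n))
        opts = FitOptions(hyper_mean=np.log(prec), hyper_variance=1e-10,
                          tolerance=1e-8)
        post = variational_laplace(lambda th: th @ X.T, y, prior, opts)
        post.diagnostics["n_theta"] = 0
        design = ConditionDesign("toy", [ConditionGroup(f"g{k}", (k,), 1.0)
                                         for k in range(3)], 3)
        results = exhaustive_bmr_search(post, design)
        assert len(results) == 8
        best_mask = results[0][0]
        assert best_mask[0] and best_mask[1] and not best_mask[2]
        full_dF = dict(results)[(True, True, True)]
        assert full_dF == 0.0

    def test_group_count_cap(self):
        from ldcm.group import exhaustive_bmr_search
        from ldcm.longitudinal import ConditionDesign, ConditionGroup
        n = 20
        post = Posterior(mean=np.zeros(n), covariance=np.eye(n),
                         hyper=np.zeros(1), free_energy=0.0,
                         prior=PriorDensity(np.zeros(n), np.eye(n)),
                         diagnostics={"n_theta": 0})
        design = ConditionDesign("big", [ConditionGroup(f"g{k}", (k,), 1.0)
                                         for k in range(n)], n)
        with pytest.raises(DesignError):
            exhaustive_bmr_search(post, design)


class TestBms:
    def test_equal_evidence_uniform(self):
        table = ModelEvidenceTable(np.zeros((5, 4)), list("abcd"))
        res = fixed_effects_bms(table)
        assert np.allclose(res["probabilities"], 0.25)

    def test_log_bayes_factor_ratio(self):
        table = ModelEvidenceTable(np.array([[np.log(20.0), 0.0]]), ["m1", "m2"])
        res = fixed_effects_bms(table)
        assert res["probabilities"][0] / res["probabilities"][1] == pytest.approx(20.0)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(-50, 50), st.integers(0, 100))
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((3, 4))
        p1 = fixed_effects_bms(ModelEvidenceTable(F, list("abcd")))["probabilities"]
        p2 = fixed_effects_bms(ModelEvidenceTable(F + shift, list("abcd")))["probabilities"]
        assert np.allclose(p1, p2)
        assert p1.sum() == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            ModelEvidenceTable(np.zeros((0, 2)), ["a", "b"])


class TestZscore:
    def test_mean_zero_sd_one(self):
        z = zscore_regressor([71.0, 80.0, 64.5, 90.0, 77.7])
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_two_subjects_give_unit_values(self):
        assert np.allclose(sorted(zscore_regressor([3.0, 7.0])), [-1.0, 1.0])

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.1, 50), st.floats(-100, 100), st.integers(0, 50))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(10)
        assert np.allclose(zscore_regressor(v), zscore_regressor(a * v + b))

    def test_constant_input_rejected(self):
        with pytest.raises(DesignError):
            zscore_regressor([5.0, 5.0, 5.0])


class TestGroupDesign:
    def test_first_column_must_be_ones(self):
        with pytest.raises(DesignError):
            GroupDesign(np.array([[2.0, 1.0], [1.0, 0.0]]), ["mean", "x"])

    def test_rank_deficient_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(DesignError):
            GroupDesign(X, ["mean", "dup"])


class TestPeb:
    def _posterior_set(self, means, cov_scale=0.01, prior_var=1.0):
        k = len(means[0])
        prior = PriorDensity(np.zeros(k), np.eye(k) * prior_var)
        posts = []
        for m in means:
            posts.append(Posterior(
                mean=np.asarray(m, dtype=float),
                covariance=np.eye(k) * cov_scale,
                hyper=np.zeros(1), free_energy=0.0, prior=prior,
                diagnostics={"n_theta": 0}))
        return posts

    def test_degenerate_cohort_recovers_shared_value(self):
        shared = np.array([0.4, -0.3])
        posts = self._posterior_set([shared] * 8)
        design = GroupDesign(np.ones((8, 1)), ["mean"])
        res = peb_fit(posts, design)
        assert np.allclose(res.beta_matrix()[0], shared, atol=0.02)
        # between-subject variance collapses towards its lower bound
        assert np.all(np.diag(res.between_cov) < 0.01)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(0)
        means = list(0.3 + 0.1 * rng.standard_normal((6, 2)))
        covariate = rng.standard_normal(6)
        posts = self._posterior_set(means)
        X = np.column_stack([np.ones(6), zscore_regressor(covariate)])
        res1 = peb_fit(posts, GroupDesign(X, ["mean", "cov"]))
        perm = rng.permutation(6)
        res2 = peb_fit([posts[i] for i in perm],
                       GroupDesign(X[perm], ["mean", "cov"]))
        assert np.allclose(res1.beta.mean, res2.beta.mean, atol=1e-6)

    def test_covariate_slope_recovered(self):
        rng = np.random.default_rng(1)
        n, k = 30, 2
        z = zscore_regressor(rng.standard_normal(n))
        slope = np.array([0.5, 0.0])
        means = [slope * zi + 0.05 * rng.standard_normal(k) for zi in z]
        posts = self._posterior_set(means, cov_scale=0.005)
        res = peb_fit(posts, GroupDesign(np.column_stack([np.ones(n), z]),
                                         ["mean", "z"]))
        beta = res.beta_matrix()
        assert beta[1, 0] == pytest.approx(0.5, abs=0.1)
        assert abs(beta[1, 1]) < 0.1
        assert res.posterior_sign_probability()[1, 0] > 0.95

    def test_design_row_mismatch_rejected(self):
        posts = self._posterior_set([np.zeros(2)] * 3)
        with pytest.raises(DesignError):
            peb_fit(posts, GroupDesign(np.ones((4, 1)), ["mean"]))


class TestBma:
    def _post(self, mean, var, F=0.0):
        m = np.atleast_1d(np.asarray(mean, dtype=float))
        return Posterior(mean=m, covariance=np.eye(m.size) * var,
                         hyper=np.zeros(1), free_energy=F,
                         prior=PriorDensity(np.zeros(m.size), np.eye(m.size)))

    def test_single_model_identity(self):
        p = self._post([1.0, 2.0], 0.3)
        out = bma([p], [1.0])
        assert np.allclose(out.mean, p.mean)
        assert np.allclose(out.covariance, p.covariance)

    def test_symmetric_mixture_total_variance(self):
        m = 0.8
        p1, p2 = self._post([m], 0.1), self._post([-m], 0.1)
        out = bma([p1, p2], [0.5, 0.5])
        assert out.mean[0] == pytest.approx(0.0)
        assert out.covariance[0, 0] == pytest.approx(0.1 + m ** 2)

    def test_weights_from_bms_compose(self):
        posts = [self._post([1.0], 0.1, F=2.0), self._post([0.0], 0.1, F=0.0)]
        table = ModelEvidenceTable(np.array([[2.0, 0.0]]), ["a", "b"])
        w = fixed_effects_bms(table)["probabilities"]
        out = bma(posts, w)
        expected = w[0] * 1.0 + w[1] * 0.0
        assert out.mean[0] == pytest.approx(expected)

    def test_invalid_weights_rejected(self):
        posts = [self._post([0.0], 0.1), self._post([1.0], 0.1)]
        with pytest.raises(DataError):
            bma(posts, [0.7, 0.7])
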