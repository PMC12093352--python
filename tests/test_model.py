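import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldcm.config import CircuitConfig, default_config
from ldcm.exceptions import FixedPointError, LayoutError
from ldcm.model import (
    ModelVariant,
    ParameterVector,
    default_priors,
    scale_parameters,
    firing_rate,
    nmda_gate,
    flow,
    flow_jacobian,
    fixed_point,
    fixed_point_batch,
    get_layout,
)


class TestLayout:
    def test_variant_grid_layouts(self):
        base = get_layout(ModelVariant(n_regions=4))
        dual = get_layout(ModelVariant(dual_glutamate=True, n_regions=4))
        rstl = get_layout(ModelVariant(regional_stl=True, n_regions=4))
        assert "H" in base.blocks and "Hi" not in base.blocks
        assert {"Hi", "Hnmda", "Hampa"} <= set(dual.blocks) and "H" not in dual.blocks
        assert base.blocks["J"][1] == (2,)
        assert rstl.blocks["J"][1] == (4, 2)

    def test_invalid_region_count(self):
        with pytest.raises(LayoutError):
            ModelVariant(n_regions=0)

    def test_layout_mismatch_names_block(self):
        v2 = ModelVariant(n_regions=2)
        theta = ParameterVector.default(v2)
        with pytest.raises(LayoutError):
            scale_parameters(theta, ModelVariant(n_regions=4))


class TestPriors:
    @pytest.mark.parametrize("block,var", [
        ("kappa", 1 / 16), ("C", 1 / 16), ("H", 1 / 32), ("A", 1 / 8),
        ("AN", 1 / 8), ("L", 64.0), ("J", 1 / 16), ("a", 1 / 128),
        ("d", 1 / 128), ("b", 1 / 128), ("c", 1 / 128), ("f", 1 / 128),
        ("D", 1 / 64),
    ])
    def test_template_variances(self, block, var):
        v = ModelVariant(n_regions=4)
        prior = default_priors(v)
        idx = get_layout(v).indices(block)
        assert np.allclose(prior.variances[idx], var)

    def test_means_zero_except_leadfield(self):
        v = ModelVariant(dual_glutamate=True, n_regions=4)
        prior = default_priors(v)
        layout = get_layout(v)
        sl = layout.blocks["L"][0]
        assert np.allclose(prior.mean[sl], 1.0)
        rest = np.ones(layout.n_params, dtype=bool)
        rest[sl] = False
        assert np.allclose(prior.mean[rest], 0.0)

    def test_dual_variant_intrinsic_variances(self):
        v = ModelVariant(dual_glutamate=True, n_regions=4)
        prior = default_priors(v)
        layout = get_layout(v)
        for block in ("Hi", "Hnmda", "Hampa"):
            assert np.allclose(prior.variances[layout.indices(block)], 1 / 32)

    def test_prior_yaml_round_trip(self, tmp_path):
        v = ModelVariant(n_regions=2)
        prior = default_priors(v)
        path = tmp_path / "prior.yaml"
        prior.to_yaml(path)
        from ldcm.model import PriorDensity
        back = PriorDensity.from_yaml(path)
        assert np.allclose(back.mean, prior.mean)
        assert np.allclose(back.covariance, prior.covariance)

    def test_prior_sampling_positive_physical_quantities(self):
        v = ModelVariant(n_regions=2)
        prior = default_priors(v)
        rng = np.random.default_rng(0)
        theta = prior.sample(rng, size=50)
        sp = scale_parameters(theta, v)
        assert np.all(sp.kappa > 0)
        assert np.all(sp.C > 0)
        assert np.all(sp.delays > 0)


class TestScaleParameters:
    def test_zero_theta_reproduces_templates(self):
        cfg = default_config()
        v = ModelVariant(n_regions=4)
        sp = scale_parameters(ParameterVector.default(v), v)
        assert np.allclose(sp.kappa, (4.0, 16.0, 100.0))
        assert np.allclose(sp.C, np.array([128, 128, 256, 32]) / 1000)
        assert np.allclose(sp.delays, (2.0, 16.0))
        assert np.allclose(sp.G_gaba[0] + sp.G_ampa[0], cfg.h_default)
        assert np.allclose(sp.G_ampa[0], sp.G_nmda[0])
        a_t = np.array(cfg.a_template) / 8.0
        assert np.allclose(sp.A[0], a_t) and np.allclose(sp.AN[0], a_t)

    def test_log_scaling_of_rate_constants(self):
        v = ModelVariant(n_regions=2)
        layout = get_layout(v)
        vec = ParameterVector.default(v).values.copy()
        vec[layout.indices("kappa")[0]] = np.log(2.0)
        sp = scale_parameters(vec, v)
        assert np.isclose(sp.kappa[0], 8.0)

    def test_variants_agree_at_prior_mean(self):
        mono = ModelVariant(n_regions=3)
        dual = ModelVariant(dual_glutamate=True, n_regions=3)
        sm = scale_parameters(ParameterVector.default(mono), mono)
        sd_ = scale_parameters(ParameterVector.default(dual), dual)
        for field in ("G_gaba", "G_ampa", "G_nmda"):
            assert np.allclose(getattr(sm, field), getattr(sd_, field))


class TestNonlinearities:
    def test_firing_rate_midpoint_and_saturation(self):
        cfg = default_config()
        assert np.isclose(firing_rate(cfg.sigmoid_threshold), 0.5)
        assert firing_rate(-1e4) < 1e-10
        assert firing_rate(1e4) > 1 - 1e-10

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-120, 80), st.floats(-120, 80))
    def test_firing_rate_monotone_bounded(self, v1, v2):
        lo, hi = sorted((v1, v2))
        r1, r2 = firing_rate(lo), firing_rate(hi)
        assert 0.0 <= r1 <= r2 <= 1.0

    def test_firing_rate_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            firing_rate(0.0, slope=-1.0)

    def test_nmda_gate_range_and_derivative(self):
        V = np.linspace(-100, 60, 321)
        g = nmda_gate(V)
        assert np.all((g > 0) & (g < 1))
        assert nmda_gate(-70.0) < nmda_gate(0.0)
        # numerical-derivative oracle: strictly increasing everywhere
        dg = np.diff(g) / np.diff(V)
        assert np.all(dg > 0)


class TestFlow:
    def test_leak_only_relaxes_to_leak_reversal(self, variant2):
        cfg = default_config()
        quiet = CircuitConfig(background_drive=0.0)
        vec = ParameterVector.default(variant2).values.copy()
        layout = get_layout(variant2)
        # remove all couplings by pushing log-gains to -inf equivalent
        for block in ("H", "A", "AN"):
            vec[layout.indices(block)] = -30.0
        sp = scale_parameters(vec, variant2, quiet)
        st_ = fixed_point(sp)
        assert np.allclose(st_.V, quiet.v_leak, atol=1e-4)

    def test_capacitance_scaling_halves_voltage_derivative(self, variant2):
        layout = get_layout(variant2)
        base = ParameterVector.default(variant2).values
        doubled = base.copy()
        doubled[layout.indices("C")] = np.log(2.0)
        sp1 = scale_parameters(base, variant2)
        sp2 = scale_parameters(doubled, variant2)
        x = np.tile([-60.0, 0.5, 0.4, 0.3], 8)  # arbitrary state
        f1 = flow(x, sp1).reshape(2, 4, 4)
        f2 = flow(x, sp2).reshape(2, 4, 4)
        assert np.allclose(f2[..., 0], f1[..., 0] / 2)
        assert np.allclose(f2[..., 1:], f1[..., 1:])

    def test_flow_rejects_non_finite_state(self, variant2):
        sp = scale_parameters(ParameterVector.default(variant2), variant2)
        x = np.full(32, np.nan)
        with pytest.raises(FloatingPointError):
            flow(x, sp)

    def test_jacobian_methods_agree(self, variant2, stable_theta2):
        sp = scale_parameters(stable_theta2, variant2)
        x = fixed_point(sp).flat
        Ja = flow_jacobian(x, sp, method="analytic")
        Jc = flow_jacobian(x, sp, method="central")
        Jx = flow_jacobian(x, sp, method="complex")
        scale = np.abs(Jx).max()
        assert np.abs(Ja - Jx).max() / scale < 1e-12
        assert np.abs(Jc - Jx).max() / scale < 1e-8

    def test_jacobian_exact_for_linear_flow(self):
        # central differences reproduce the matrix of a linear system exactly
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 6))
        f = lambda x: x @ A.T
        x0 = rng.standard_normal(6)
        step = 1e-4
        J = np.empty((6, 6))
        for j in range(6):
            e = np.zeros(6)
            e[j] = step
            J[:, j] = (f(x0 + e) - f(x0 - e)) / (2 * step)
        assert np.allclose(J, A, atol=1e-10)


class TestFixedPoint:
    def test_default_residual_and_nonnegative_conductances(self, variant4):
        sp = scale_parameters(ParameterVector.default(variant4), variant4)
        st_ = fixed_point(sp)
        resid = np.abs(flow(st_.flat, sp)).max()
        assert resid < 1e-8
        assert np.all(st_.conductances >= 0)

    def test_symmetry_across_regions(self, variant4):
        # identical regional parameters give identical regional fixed points
        sp = scale_parameters(ParameterVector.default(variant4), variant4)
        st_ = fixed_point(sp)
        for r in range(1, 4):
            assert np.allclose(st_.values[r], st_.values[0], atol=1e-10)

    def test_prior_sample_convergence_rate(self, variant4):
        prior = default_priors(variant4)
        rng = np.random.default_rng(7)
        theta = prior.sample(rng, size=100)
        sp = scale_parameters(theta, variant4)
        _, ok, resid = fixed_point_batch(sp)
        assert resid[ok].max() < 1e-6
        # allow up to 5% flagged non-convergence, never silent failure
        assert ok.mean() >= 0.95

    def test_nonconvergence_raises_with_residual(self, variant2):
        sp = scale_parameters(ParameterVector.default(variant2), variant2)
        with pytest.raises(FixedPointError) as err:
            fixed_point(sp, max_iter=1, tol=1e-16)
        assert err.value.residual is not None
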