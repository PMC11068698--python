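import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from spikefrr import (Impulse, ModelSpec, ShapeParameterError, SpikeShape,
                      boxcar_ft, clamp_refractory_ft_lif,
                      refractory_current_ft, solve_alpha_params)


class TestAlphaParams:
    @pytest.mark.parametrize(
        "kappa, delta_v, tau_ref, t0_expected, beta_expected, tol_t0, tol_beta",
        [
            # printed parameter sets of the alpha action potential
            (800.0, 0.01, 0.3, 12.6e-4, 33.6, 0.05e-4, 0.05),
            (2500.0, 0.01, 0.1, 4.0e-4, 101.3, 0.05e-4, 0.05),
        ],
    )
    def test_printed_parameter_sets(self, kappa, delta_v, tau_ref,
                                    t0_expected, beta_expected, tol_t0, tol_beta):
        t0, beta = solve_alpha_params(kappa, delta_v, tau_ref, v_T=1.0, v_R=0.0)
        assert t0 == pytest.approx(t0_expected, abs=tol_t0)
        assert beta == pytest.approx(beta_expected, abs=tol_beta)

    @settings(max_examples=60, deadline=None)
    @given(
        kappa=st.floats(10.0, 5000.0),
        delta_v=st.floats(1e-3, 0.5),
        tau_ref=st.floats(0.01, 1.0),
        v_R=st.floats(-0.4, 0.5),
    )
    def test_boundary_conditions_always_hold(self, kappa, delta_v, tau_ref, v_R):
        v_T = 1.0
        try:
            shape = SpikeShape.alpha(kappa, delta_v, tau_ref, v_T, v_R)
        except ShapeParameterError:
            return  # invalid parameter combination correctly rejected
        assert shape.value(0.0) == pytest.approx(v_T, abs=1e-9)
        assert shape.value(tau_ref) == pytest.approx(v_R, abs=1e-9)

    def test_unreachable_reset_raises(self):
        # a reset above the waveform's reach cannot be hit at tau_ref
        with pytest.raises(ShapeParameterError):
            solve_alpha_params(kappa=1e-3, delta_v=0.01, tau_ref=0.1,
                               v_T=1.0, v_R=2.0)
        with pytest.raises(ShapeParameterError):
            solve_alpha_params(kappa=-5.0, delta_v=0.01, tau_ref=0.1)
        with pytest.raises(ShapeParameterError):
            solve_alpha_params(kappa=800.0, delta_v=-0.5, tau_ref=0.1, v_R=0.0)


class TestEvaluation:
    @pytest.fixture(scope="class")
    def alpha(self):
        return SpikeShape.alpha(800.0, 0.01, 0.3)

    def test_alpha_value_direct_arithmetic(self, alpha):
        t = 0.01
        expected = 800.0 * (t + alpha.t0) * math.exp(-alpha.beta * t) - 0.01
        assert alpha.value(t) == pytest.approx(expected, rel=1e-12)

    def test_alpha_derivative_matches_finite_difference(self, alpha):
        t, h = 0.05, 1e-6
        fd = (alpha.value(t + h) - alpha.value(t - h)) / (2 * h)
        assert alpha.derivative(t) == pytest.approx(fd, rel=1e-6)

    def test_alpha_derivative_stationary_point(self, alpha):
        t_star = 1.0 / alpha.beta - alpha.t0
        assert alpha.derivative(t_star) == pytest.approx(0.0, abs=1e-12)

    def test_clamp_constant_segment_and_impulse(self):
        clamp = SpikeShape.clamp(0.2, v_T=1.0, v_R=-0.1)
        assert clamp.derivative(0.1) == 0.0
        assert clamp.value(0.0) == 1.0
        assert clamp.value(0.05) == -0.1
        imp = clamp.derivative(0.0)
        assert isinstance(imp, Impulse)
        assert imp.weight == pytest.approx(-1.1)
        assert clamp.impulse == Impulse(0.0, -1.1)

    def test_domain_error(self, alpha):
        with pytest.raises(ValueError):
            alpha.value(-0.01)
        with pytest.raises(ValueError):
            alpha.value(0.31)

    def test_tabulated_interpolation_roundtrip(self, alpha, tmp_path):
        t = np.linspace(0, 0.3, 601)
        tab = SpikeShape.tabulated(t, alpha.value(t), alpha.derivative(t))
        assert tab.value(0.1234) == pytest.approx(alpha.value(0.1234), abs=1e-4)
        path = tmp_path / "shape.txt"
        tab.write_table(path)
        back = SpikeShape.read_table(path)
        assert back.value(0.2) == pytest.approx(alpha.value(0.2), abs=1e-4)

    def test_config_roundtrip(self, alpha):
        back = SpikeShape.from_config(alpha.to_config())
        assert back.beta == pytest.approx(alpha.beta)
        clamp = SpikeShape.clamp(0.1)
        assert SpikeShape.from_config(clamp.to_config()).kind == "clamp"


class TestBoxcarFT:
    def test_zero_frequency_limit(self):
        assert boxcar_ft(0.25, 0.0) == pytest.approx(0.25)

    def test_full_period_null(self):
        tau = 0.3
        assert abs(boxcar_ft(tau, 2 * np.pi / tau)) < 1e-12

    def test_against_quadrature(self):
        tau, w = 0.5, 1.0
        re, _ = quad(lambda t: math.cos(w * t), 0, tau)
        im, _ = quad(lambda t: math.sin(w * t), 0, tau)
        assert boxcar_ft(tau, w) == pytest.approx(re + 1j * im, rel=1e-10)

    def test_conjugate_symmetry(self):
        w = np.linspace(0.1, 50, 37)
        plus = boxcar_ft(0.17, w)
        minus = boxcar_ft(0.17, -w)
        np.testing.assert_allclose(minus, np.conj(plus), rtol=1e-12)


class TestRefractoryCurrentFT:
    def test_clamp_closed_form_zero_frequency(self):
        # omega -> 0 limit: (mu - v_R)*tau_ref plus full impulse weight
        val = clamp_refractory_ft_lif(0.8, 1.0, 0.0, 0.1, 0.0)
        assert complex(val) == pytest.approx(0.8 * 0.1 + 1.0)

    def test_clamp_continuity_at_small_omega(self):
        shape = SpikeShape.clamp(0.1)
        model = ModelSpec(mu=0.8, shape=shape)
        fi = refractory_current_ft(shape, model, np.array([1e-6, 2e-6]))
        lim = 0.8 * 0.1 + 1.0
        np.testing.assert_allclose(fi.values, lim, rtol=1e-5)

    def test_vanishing_interval_limit(self):
        val = clamp_refractory_ft_lif(0.8, 1.0, 0.0, 1e-9, 3.0)
        assert complex(val) == pytest.approx(1.0, abs=1e-6)

    def test_quadrature_matches_closed_form_for_near_clamp_alpha(self):
        # a steeply decaying alpha shape approaches the clamp: transforms
        # agree to ~2% (the residual is the area of the brief voltage pulse)
        shape = SpikeShape.alpha(kappa=60.0, delta_v=1e-6, tau_ref=0.1)
        model = ModelSpec(mu=0.8, shape=shape)
        w = np.array([1.0])
        fi = refractory_current_ft(shape, model, w, n_quad=2**15 + 1)
        ref = clamp_refractory_ft_lif(0.8, 1.0, 0.0, 0.1, w)
        assert abs(fi.values[0] - ref[0]) / abs(ref[0]) < 0.02

    def test_clamp_quadrature_path_with_impulse_bookkeeping(self):
        # generic quadrature on the clamp's constant segment + impulse must
        # reproduce the closed form to high accuracy
        shape = SpikeShape.clamp(0.1)
        w = np.linspace(0.5, 40, 23)
        seg = (0.8 - 0.0) * np.asarray(boxcar_ft(0.1, w))
        manual = seg + (-shape.impulse.weight) * np.exp(1j * w * 0.0)
        closed = clamp_refractory_ft_lif(0.8, 1.0, 0.0, 0.1, w)
        np.testing.assert_allclose(manual, closed, rtol=1e-8)

    def test_alpha_quadrature_against_scipy(self):
        shape = SpikeShape.alpha(2500.0, 0.01, 0.1)
        model = ModelSpec(mu=0.8, shape=shape)
        w = 3.0

        def integrand_re(t):
            g = (0.8 - shape.value(t)) - shape.derivative(t)
            return g * math.cos(w * t)

        def integrand_im(t):
            g = (0.8 - shape.value(t)) - shape.derivative(t)
            return g * math.sin(w * t)

        re, _ = quad(integrand_re, 0, 0.1, limit=200)
        im, _ = quad(integrand_im, 0, 0.1, limit=200)
        fi = refractory_current_ft(shape, model, np.array([w]), n_quad=2**13 + 1)
        assert fi.values[0] == pytest.approx(re + 1j * im, rel=1e-7)

    def test_negated_convention(self):
        shape = SpikeShape.clamp(0.1)
        model = ModelSpec(mu=0.8, shape=shape)
        w = np.array([1.0, 2.0])
        a = refractory_current_ft(shape, model, w)
        b = refractory_current_ft(shape, model, w, sign_convention="negated")
        np.testing.assert_allclose(b.values, -a.values)
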