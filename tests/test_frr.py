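import math

import numpy as np
import pytest

from spikefrr import (AUDITED_CONVENTION, Convention, ModelSpec, NoiseSpec,
                      SimConfig, SpikeShape, Susceptibility,
                      accumulate_ensemble, approx_triple_term,
                      audit_conventions, boxcar_ft, c1_constant,
                      derived_constants, estimate_susceptibility_fn,
                      eta_ref_mean_formula, frr_colored_chi, frr_colored_sxv,
                      frr_white_chi, frr_white_sxv, general_relation_residual,
                      naive_recover_no_refractory, naive_recover_white_form,
                      recover_noise_spectrum, refractory_current_ft,
                      spike_current_integral, simulate_if, triple_term)
from spikefrr.shapes import RefractoryCurrentFT
from spikefrr.spectra import Spectrum

SHAPE = SpikeShape.clamp(0.1)
MODEL = ModelSpec(mu=0.8, shape=SHAPE)


def _fake_spectra(rng, n=64, T=16.0):
    omega = 2 * np.pi * np.arange(1, n + 1) / T
    mk = lambda pair: Spectrum(
        omega=omega,
        values=rng.standard_normal(n) + 1j * rng.standard_normal(n),
        n_windows=100, pair=pair,
        se=(np.abs(rng.standard_normal(n)) + 1j * np.abs(rng.standard_normal(n))) * 1e-3)
    S_xv = mk(("x", "v"))
    S_xx = mk(("x", "x"))
    S_xx.values = np.abs(S_xx.values.real) + 0j
    FI = refractory_current_ft(SHAPE, MODEL, omega)
    return omega, S_xv, S_xx, FI


class TestScalars:
    def test_clamp_spike_current_integral_closed_form(self):
        val = spike_current_integral(SHAPE, MODEL)
        assert val == pytest.approx(0.8 * 0.1 + 1.0)

    def test_alpha_spike_current_integral_against_quadrature(self):
        from scipy.integrate import quad

        shape = SpikeShape.alpha(2500.0, 0.01, 0.1)
        model = ModelSpec(mu=0.8, shape=shape)
        ref, _ = quad(lambda t: (0.8 - shape.value(t)) - shape.derivative(t),
                      0, 0.1, limit=200)
        assert spike_current_integral(shape, model) == pytest.approx(ref, rel=1e-6)

    def test_c1_zero_rate(self):
        assert c1_constant(0.5, 0.0, SHAPE, MODEL) == 0.0

    def test_c1_deterministic_value(self):
        # C1 = r0*(<f(v)> + r0*FI(0)) with the audited impulse bookkeeping
        r0, mean_fv = 0.36, 0.45
        expected = r0 * (mean_fv + r0 * (0.8 * 0.1 + 1.0))
        assert c1_constant(mean_fv, r0, SHAPE, MODEL) == pytest.approx(expected)

    def test_eta_ref_formula_balanced_construction_is_zero(self):
        r0 = 0.3
        mean_fv = r0 * spike_current_integral(SHAPE, MODEL)
        assert eta_ref_mean_formula(MODEL, SHAPE, r0, mean_fv) == pytest.approx(0.0)

    def test_eta_ref_formula_undefined_at_zero_rate(self):
        with pytest.raises(ValueError):
            eta_ref_mean_formula(MODEL, SHAPE, 0.0, 0.3)


class TestAlgebraicRoundTrips:
    def test_white_chi_sxv_round_trip_is_identity(self, rng):
        omega, S_xv, S_xx, FI = _fake_spectra(rng)
        D = 0.1
        rep = frr_white_chi(S_xv, None, S_xx, FI, D, r0=0.3)
        chi = Susceptibility(omega=omega, values=rep.predicted,
                             se=np.zeros(omega.size, complex), method="x",
                             mask=np.ones(omega.size, bool))
        back = frr_white_sxv(chi, S_xx, FI, D)
        np.testing.assert_allclose(back.values, S_xv.values, rtol=1e-12)

    def test_colored_chi_sxv_round_trip_is_identity(self, rng):
        omega, S_xv, S_xx, FI = _fake_spectra(rng)
        noise = NoiseSpec.ou(1.0, 0.5)
        consts = derived_constants(MODEL, SHAPE, r0=0.3, mean_v=0.45,
                                   mean_fv=0.35)
        rep = frr_colored_chi(S_xv, None, S_xx, FI, noise, consts)
        chi = Susceptibility(omega=omega, values=rep.predicted,
                             se=np.zeros(omega.size, complex), method="x",
                             mask=np.ones(omega.size, bool))
        back = frr_colored_sxv(chi, noise, S_xx, FI, consts.eta_ref_mean)
        np.testing.assert_allclose(back.values, S_xv.values, rtol=1e-12)

    def test_colored_relation_reduces_to_white_for_flat_spectrum(self, rng):
        omega, S_xv, S_xx, FI = _fake_spectra(rng)
        D = 0.1
        white = NoiseSpec.white(D)
        consts = derived_constants(MODEL, SHAPE, r0=0.3, mean_v=0.45,
                                   mean_fv=0.35)
        consts.eta_ref_mean = 0.0  # white-noise limit
        colored = frr_colored_chi(S_xv, None, S_xx, FI, white, consts)
        plain = frr_white_chi(S_xv, None, S_xx, FI, D, r0=0.3)
        np.testing.assert_allclose(colored.predicted, plain.predicted, rtol=1e-12)

    def test_recoveries_differ_by_exactly_the_triple_closure_term(self, rng):
        omega, S_xv, S_xx, FI = _fake_spectra(rng)
        conv = AUDITED_CONVENTION
        chi = Susceptibility(
            omega=omega,
            values=rng.standard_normal(omega.size) + 1j * rng.standard_normal(omega.size),
            se=np.full(omega.size, 1e-6 + 1e-6j), method="x",
            mask=np.ones(omega.size, bool))
        consts = derived_constants(MODEL, SHAPE, r0=0.3, mean_v=0.45,
                                   mean_fv=0.35)
        full = recover_noise_spectrum(chi, S_xv, S_xx, FI, consts, MODEL)
        white_form = naive_recover_white_form(chi, S_xv, S_xx, FI)
        bt = conv.c_f(np.asarray(boxcar_ft(SHAPE.tau_ref, omega)))
        expected_gap = consts.eta_ref_mean * bt * S_xx.values.real / chi.values
        np.testing.assert_allclose(full.values - white_form.values,
                                   conv.sign * expected_gap, rtol=1e-10)

    def test_no_refractory_recovery_is_tau_ref_to_zero_limit(self, rng):
        omega, S_xv, S_xx, _ = _fake_spectra(rng)
        tiny = SpikeShape.clamp(1e-7)
        model = ModelSpec(mu=0.8, shape=tiny)
        FI_tiny = refractory_current_ft(tiny, model, omega)
        chi = Susceptibility(omega=omega, values=np.full(omega.size, 0.5 + 0.1j),
                             se=np.full(omega.size, 1e-6 + 1e-6j), method="x",
                             mask=np.ones(omega.size, bool))
        a = naive_recover_white_form(chi, S_xv, S_xx, FI_tiny)
        b = naive_recover_no_refractory(chi, S_xv, S_xx, 1.0, 0.0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-5)

    def test_approx_triple_term_limits(self):
        omega = np.linspace(0.01, 10, 50)
        S_xx = Spectrum(omega=omega, values=np.full(50, 0.4 + 0j),
                        n_windows=10, pair=("x", "x"))
        assert not approx_triple_term(S_xx, 0.3, 0.0, 0.1).any()
        vals = approx_triple_term(S_xx, 0.3, 1.5, 0.1)
        low = 1.5 * 0.1 * 0.4
        assert vals[0] == pytest.approx(low, rel=1e-3)


class TestConventionAudit:
    @pytest.fixture(scope="class")
    def audits(self):
        return [audit_conventions(seed=s, n_windows=128, n_windows_probe=768)
                for s in (0, 1)]

    def test_unique_winner(self, audits):
        for res in audits:
            assert res.margin > 1.5

    def test_stable_across_seeds_and_matches_frozen_constant(self, audits):
        assert audits[0].best == audits[1].best
        assert audits[0].best == AUDITED_CONVENTION

    def test_frozen_convention_orientation(self):
        assert AUDITED_CONVENTION == Convention(sign=1, conj_fi=True,
                                                conj_sxv=True)


class TestGeneralRelation:
    def test_all_zero_inputs_give_zero_residual(self):
        omega = np.linspace(0.1, 5, 20)
        zero = Spectrum(omega=omega, values=np.zeros(20, complex),
                        n_windows=4, pair=("x", "v"))
        zero_xx = Spectrum(omega=omega, values=np.zeros(20, complex),
                           n_windows=4, pair=("x", "x"))
        FI = refractory_current_ft(SHAPE, MODEL, omega)
        FI = RefractoryCurrentFT(omega_grid=omega,
                                 values=np.zeros(20, complex), shape=SHAPE)
        chi = Susceptibility(omega=omega, values=np.zeros(20, complex),
                             se=np.zeros(20, complex), method="x",
                             mask=np.ones(20, bool))
        from spikefrr.spectra import TripleTerm

        triple = TripleTerm(omega=omega, values=np.zeros(20, complex),
                            se=np.zeros(20, complex), n_windows=4)
        res = general_relation_residual(chi, zero, zero, zero_xx, FI, triple,
                                        NoiseSpec.white(0.1))
        np.testing.assert_allclose(res, 0.0)

    def test_white_noise_residual_consistent_with_zero(self):
        # pre-approximation relation with the empirical triple term closes
        noise = NoiseSpec.white(0.1)
        cfg = SimConfig(dt=1e-3, window_steps=2**13, n_windows=192, seed=31)
        out = simulate_if(MODEL, noise, None, cfg)
        from spikefrr.spectra import spectra_from_output

        specs = spectra_from_output(out, [("x", "v"), ("x", "x"), ("eta", "x")])
        chi = estimate_susceptibility_fn(out, noise)
        FI = refractory_current_ft(SHAPE, MODEL, specs[("x", "v")].omega)
        triple = triple_term(out)
        res = general_relation_residual(chi, specs[("x", "v")], None,
                                        specs[("x", "x")], FI, triple, noise)
        band = (chi.omega > 0.5) & (chi.omega < 9.0)
        rel = np.abs(res[band]) / np.abs(chi.values[band])
        assert np.median(rel) < 0.25


class TestEtaRefCrossChecks:
    def test_formula_and_empirical_agree_for_white_noise(self):
        noise = NoiseSpec.white(0.1)
        cfg = SimConfig(dt=1e-3, window_steps=2**14, n_windows=256, seed=33)
        acc = accumulate_ensemble(MODEL, noise, None, cfg,
                                  pairs=[("x", "x")], chunk_windows=128)
        consts = derived_constants(MODEL, SHAPE, acc.r0, acc.mean_v,
                                   acc.mean_fv, acc.mean_fv_se, acc.r0_se)
        emp, emp_se = acc.eta_ref_mean()
        # both must be statistically compatible with zero
        assert abs(emp) < 4 * emp_se
        assert abs(consts.eta_ref_mean) < 4 * consts.eta_ref_mean_se

    def test_formula_and_empirical_agree_for_colored_noise(self):
        tau_c = 1.0
        shape = SpikeShape.clamp(0.1)
        model = ModelSpec(mu=0.8, shape=shape)
        noise = NoiseSpec.ou(1.0, tau_c)
        cfg = SimConfig(dt=1e-3, window_steps=2**14, n_windows=512, seed=34)
        acc = accumulate_ensemble(model, noise, None, cfg,
                                  pairs=[("x", "x")], chunk_windows=128)
        consts = derived_constants(model, shape, acc.r0, acc.mean_v,
                                   acc.mean_fv, acc.mean_fv_se, acc.r0_se)
        emp, emp_se = acc.eta_ref_mean()
        assert emp > 0  # positive excursions trigger the spikes
        combined = math.hypot(emp_se, consts.eta_ref_mean_se)
        assert abs(consts.eta_ref_mean - emp) < 4 * combined

    def test_empirical_triple_term_matches_closure_at_low_frequency(self):
        # short-correlation-time regime: empirical triple vs closed form
        tau_c, tau_ref = 0.1, 0.01
        shape = SpikeShape.clamp(tau_ref)
        model = ModelSpec(mu=0.8, shape=shape)
        noise = NoiseSpec.ou(1.0, tau_c)
        cfg = SimConfig(dt=1e-3, window_steps=2**14, n_windows=384, seed=35)
        out = simulate_if(model, noise, None, cfg)
        tt = triple_term(out)
        from spikefrr.spectra import eta_ref_mean_empirical, estimate_spectrum

        S_xx = estimate_spectrum(out.windows("x"), out.windows("x"), out.dt)
        eta_ref, _ = eta_ref_mean_empirical(out)
        closed = approx_triple_term(S_xx, out.rate, eta_ref, tau_ref)
        low = tt.omega < 3.0
        se = np.hypot(tt.se.real[low], tt.se.imag[low])
        dev = np.abs(tt.values[low] - closed[low])
        assert np.mean(dev < 4 * se) > 0.9
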