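"""Fluctuation-response relations for refractory integrate-and-fire models.

The central identity of the package: for an IF model driven by white
Gaussian noise of intensity ``D``, the susceptibility of the firing rate is
fixed exactly by the spontaneous spectral statistics,

    chi_x(omega) = [ i*omega*S_xv - S_xf(v) + FI(omega)*S_xx ] / (2 D),

where ``FI`` is the Fourier transform of the single-spike refractory
current (module :mod:`spikefrr.shapes`).  For the leaky drift
``f(v) = mu - v`` the drift cross-spectrum collapses, ``S_xf(v) = -S_xv``,
giving the ``(1 + i*omega) S_xv`` form.  For colored Gaussian noise an
extra refractory triple correlation survives; with a noise correlation
time short against the mean ISI it is approximated by
``<eta>_ref * B_tilde(omega) * S_xx``, with ``<eta>_ref`` the mean noise
value inside refractory windows, which yields an approximate relation and
an estimator of the intrinsic noise spectrum from observable statistics.

Orientation audit
-----------------
Cross-spectra and analytic transforms enter these identities with specific
complex orientations that are easy to scramble (``S_xv`` vs its conjugate,
``FI(omega)`` vs ``FI(-omega)``, an overall sign).  Rather than trusting
any one written form, the package fixes the convention by a one-time
numerical audit: all candidate combinations are evaluated on a small
white-noise run, and the unique combination that closes the exact
white-noise relation is frozen in :data:`AUDITED_CONVENTION`.  With the
package estimator ``S_ab = <tilde_b conj(tilde_a)>/T`` and ``FI`` computed
with the ``exp(+i*omega*t)`` kernel, the winner conjugates both ``S_xv``
(and ``S_xf(v)``) and the analytic kernels ``FI``/``B_tilde``, with
positive overall sign; the same audit shows the clamp boundary impulse
must enter ``FI`` with full weight ``+(v_T - v_R)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .shapes import RefractoryCurrentFT, SpikeShape, boxcar_ft, refractory_current_ft
from .simulate import ModelSpec, NoiseSpec, SimConfig
from .spectra import Spectrum, TripleTerm
from .response import Susceptibility


@dataclass(frozen=True)
class Convention:
    """Orientation choices entering the FRR formulas.

    ``conj_sxv``: conjugate the stored cross-spectra ``S_xv``/``S_xf(v)``;
    ``conj_fi``: evaluate the analytic transforms (``FI``, ``B_tilde``, and
    the empirical triple term) at ``-omega`` (i.e. conjugate them);
    ``sign``: overall sign of the prediction.
    """

    sign: int = 1
    conj_fi: bool = True
    conj_sxv: bool = True

    def c_s(self, values: np.ndarray) -> np.ndarray:
        return np.conj(values) if self.conj_sxv else values

    def c_f(self, values: np.ndarray) -> np.ndarray:
        return np.conj(values) if self.conj_fi else values

    def label(self) -> str:
        return (f"sign={self.sign:+d}, "
                f"S_xv {'conjugated' if self.conj_sxv else 'as stored'}, "
                f"FI/B {'at -omega' if self.conj_fi else 'at +omega'}")


#: Convention selected by the white-noise audit (see :func:`audit_conventions`).
AUDITED_CONVENTION = Convention(sign=1, conj_fi=True, conj_sxv=True)


@dataclass
class DerivedConstants:
    """Stationary scalars entering the relations.

    ``eta_ref_mean_se`` is the statistical error of the formula-based
    refractory noise mean: the sample mean of the drift (equivalently of
    the voltage) fluctuates, and the formula amplifies that fluctuation by
    ``1/(r0 * tau_ref)``, which dominates for short refractory periods.
    """

    r0: float
    mean_v: float
    mean_fv: float
    eta_ref_mean: float
    C1: float
    eta_ref_mean_se: float = 0.0


@dataclass
class FRRReport:
    """Predicted vs independently measured spectral quantity."""

    omega: np.ndarray
    predicted: np.ndarray
    measured: np.ndarray
    rel_err: np.ndarray
    band: np.ndarray
    band_median_rel_err: float
    convention_audit: str
    quantity: str = "chi"

    @classmethod
    def build(cls, omega, predicted, measured, band_mask, convention: Convention,
              quantity: str = "chi", valid=None) -> "FRRReport":
        valid = np.ones(omega.shape, bool) if valid is None else valid
        denom = np.abs(measured)
        rel = np.where(denom > 0, np.abs(predicted - measured) / np.where(denom > 0, denom, 1.0),
                       np.nan)
        m = band_mask & valid & (denom > 0)
        med = float(np.median(rel[m])) if m.any() else float("nan")
        return cls(omega=omega, predicted=predicted, measured=measured,
                   rel_err=rel, band=m, band_median_rel_err=med,
                   convention_audit=convention.label(), quantity=quantity)


def default_band(r0: float) -> tuple[float, float]:
    """Summary band around the firing rate: ``[2 pi r0 / 4, 8 pi r0]``."""
    return math.pi * r0 / 2.0, 8.0 * math.pi * r0


# ---------------------------------------------------------------------------
# scalar building blocks


def spike_current_integral(shape: SpikeShape, model: ModelSpec) -> float:
    """``int_0^tau_ref [f(v_spike) - dv_spike/dt] dtau`` incl. impulse weight.

    Equals ``FI(omega=0)``; for the clamped leaky model this is
    ``(mu - v_R)*tau_ref + (v_T - v_R)``.
    """
    fi0 = refractory_current_ft(shape, model, np.array([0.0]))
    return float(fi0.values[0].real)


def c1_constant(mean_fv: float, r0: float, shape: SpikeShape, model: ModelSpec) -> float:
    """Stationary constant ``C1 = r0*[<f(v)> - r0*int(dv_spike/dt - f(v_spike))]``.

    The shape integral (with full impulse bookkeeping) is ``-FI(0)``.
    """
    if r0 == 0.0:
        return 0.0
    return r0 * (mean_fv + r0 * spike_current_integral(shape, model))


def eta_ref_mean_formula(model: ModelSpec, shape: SpikeShape, r0: float,
                         mean_fv: float) -> float:
    """Refractory-conditioned noise mean from stationary averages.

    ``<eta>_ref = (1/tau_ref) * [ <f(v)>/r0 - int_0^tau_ref
    (f(v_spike) - dv_spike/dt) dtau ]``; vanishes for white noise.  For the
    leaky drift ``<f(v)> = mu - <v>`` with the voltage average taken over
    the full trace including refractory samples.
    """
    if r0 <= 0:
        raise ValueError("eta_ref mean undefined at zero firing rate")
    tau_ref = shape.tau_ref
    return (mean_fv / r0 - spike_current_integral(shape, model)) / tau_ref


def derived_constants(model: ModelSpec, shape: SpikeShape, r0: float,
                      mean_v: float, mean_fv: float,
                      mean_fv_se: float = 0.0, r0_se: float = 0.0) -> DerivedConstants:
    eta_se = 0.0
    if r0 > 0:
        eta_se = math.hypot(mean_fv_se / r0, r0_se * mean_fv / r0**2) / shape.tau_ref
    return DerivedConstants(
        r0=r0, mean_v=mean_v, mean_fv=mean_fv,
        eta_ref_mean=eta_ref_mean_formula(model, shape, r0, mean_fv),
        C1=c1_constant(mean_fv, r0, shape, model),
        eta_ref_mean_se=eta_se,
    )


# ---------------------------------------------------------------------------
# white-noise relations (exact)


def _numerator_white(S_xv: Spectrum, S_xfv: Spectrum | None, S_xx: Spectrum,
                     FI: RefractoryCurrentFT, conv: Convention) -> np.ndarray:
    omega = S_xv.omega
    sxv = conv.c_s(S_xv.values)
    sxfv = conv.c_s(S_xfv.values) if S_xfv is not None else -sxv
    fi = conv.c_f(np.interp(omega, FI.omega_grid, FI.values.real)
                  + 1j * np.interp(omega, FI.omega_grid, FI.values.imag))
    return conv.sign * (1j * omega * sxv - sxfv + fi * S_xx.values.real)


def frr_white_chi(
    S_xv: Spectrum, S_xfv: Spectrum | None, S_xx: Spectrum,
    FI: RefractoryCurrentFT, D: float,
    measured: Susceptibility | None = None,
    convention: Convention = AUDITED_CONVENTION,
    band: tuple[float, float] | None = None,
    r0: float | None = None,
) -> FRRReport:
    """Exact white-noise FRR: predict ``chi`` from spontaneous statistics.

    ``S_xfv=None`` invokes the leaky-drift shortcut ``S_xf(v) = -S_xv``.
    The returned report pairs the prediction with ``measured`` (if given).
    """
    predicted = _numerator_white(S_xv, S_xfv, S_xx, FI, convention) / (2.0 * D)
    omega = S_xv.omega
    meas = measured.values if measured is not None else np.full(omega.shape, np.nan + 0j)
    valid = measured.mask if measured is not None else np.ones(omega.shape, bool)
    if band is None:
        band = default_band(r0) if r0 else (omega[0], omega[-1])
    bm = (omega >= band[0]) & (omega <= band[1])
    return FRRReport.build(omega, predicted, meas, bm, convention, "chi", valid)


def frr_white_sxv(
    chi: Susceptibility, S_xx: Spectrum, FI: RefractoryCurrentFT, D: float,
    convention: Convention = AUDITED_CONVENTION,
) -> Spectrum:
    """Predict the voltage/spike-train cross-spectrum from the white FRR.

    Algebraic inversion of the leaky-drift relation:
    ``S_xv = [2 D chi - FI S_xx] / (1 + i omega)`` in the audited
    orientation; the exact round trip with :func:`frr_white_chi` holds by
    construction.
    """
    omega = S_xx.omega
    fi = convention.c_f(np.interp(omega, FI.omega_grid, FI.values.real)
                        + 1j * np.interp(omega, FI.omega_grid, FI.values.imag))
    oriented = (2.0 * D * chi.values / convention.sign
                - fi * S_xx.values.real) / (1.0 + 1j * omega)
    vals = convention.c_s(oriented)  # back to the stored orientation
    return Spectrum(omega=omega, values=vals, n_windows=S_xx.n_windows,
                    pair=("x", "v"), se=None)


# ---------------------------------------------------------------------------
# colored-noise relations (approximate)


def approx_triple_term(S_xx: Spectrum, r0: float, eta_ref_mean: float,
                       tau_ref: float) -> np.ndarray:
    """Short-correlation-time closure of the refractory triple correlation.

    ``<eta>_ref * B_tilde(omega) * S_xx(omega)`` on the positive grid (the
    ``r0^2`` offset lives in the DC bin only), directly comparable with the
    empirical :func:`spikefrr.spectra.triple_term`.
    """
    bt = np.asarray(boxcar_ft(tau_ref, S_xx.omega))
    return eta_ref_mean * bt * S_xx.values.real


def frr_colored_chi(
    S_xv: Spectrum, S_xfv: Spectrum | None, S_xx: Spectrum,
    FI: RefractoryCurrentFT, noise: NoiseSpec,
    constants: DerivedConstants,
    measured: Susceptibility | None = None,
    convention: Convention = AUDITED_CONVENTION,
    band: tuple[float, float] | None = None,
) -> FRRReport:
    """Approximate colored-noise FRR for the susceptibility.

    Adds the closed triple-correlation term
    ``<eta>_ref * B_tilde * S_xx`` to the white numerator and divides by the
    noise spectrum ``S_eta_eta(omega)``.  Valid when both ``tau_c`` and
    ``tau_ref`` are short against the mean ISI.  With white noise
    (``<eta>_ref = 0``, flat spectrum) it reduces to the exact relation.
    """
    omega = S_xv.omega
    num = _numerator_white(S_xv, S_xfv, S_xx, FI, convention)
    tau_ref = FI.shape.tau_ref
    bt = convention.c_f(np.asarray(boxcar_ft(tau_ref, omega)))
    num = num + convention.sign * constants.eta_ref_mean * bt * S_xx.values.real
    see = noise.spectrum(omega)
    predicted = num / see
    meas = measured.values if measured is not None else np.full(omega.shape, np.nan + 0j)
    valid = measured.mask if measured is not None else np.ones(omega.shape, bool)
    if band is None:
        band = default_band(constants.r0)
    bm = (omega >= band[0]) & (omega <= band[1])
    return FRRReport.build(omega, predicted, meas, bm, convention, "chi", valid)


def _chi_division_mask(chi: Susceptibility, z: float = 3.0) -> np.ndarray:
    """Mask frequencies where chi is indistinguishable from zero."""
    se_mag = np.hypot(chi.se.real, chi.se.imag)
    return chi.mask & (np.abs(chi.values) > z * se_mag)


def recover_noise_spectrum(
    chi: Susceptibility, S_xv: Spectrum, S_xx: Spectrum,
    FI: RefractoryCurrentFT, constants: DerivedConstants, model: ModelSpec,
    convention: Convention = AUDITED_CONVENTION,
) -> Spectrum:
    """Estimate the intrinsic noise spectrum from observable statistics.

    Leaky-drift inversion of the approximate colored FRR:

        S_eta_eta = [ (1+i*omega) S_xv + FI S_xx
                      + <eta>_ref B_tilde S_xx ] / chi

    with ``<eta>_ref`` computed from stationary averages
    (:func:`eta_ref_mean_formula`).  The real part is the spectrum estimate;
    the imaginary residual is a diagnostic of the approximation and of
    estimation noise.  Frequencies where ``|chi|`` is below three of its
    standard errors are masked (NaN).
    """
    if not model.is_lif:
        raise ValueError("noise-spectrum recovery requires the leaky drift")
    omega = S_xv.omega
    tau_ref = FI.shape.tau_ref
    sxv = convention.c_s(S_xv.values)
    fi = convention.c_f(np.interp(omega, FI.omega_grid, FI.values.real)
                        + 1j * np.interp(omega, FI.omega_grid, FI.values.imag))
    bt = convention.c_f(np.asarray(boxcar_ft(tau_ref, omega)))
    num = convention.sign * ((1.0 + 1j * omega) * sxv
                             + (fi + constants.eta_ref_mean * bt) * S_xx.values.real)
    ok = _chi_division_mask(chi)
    vals = np.where(ok, num / np.where(ok, chi.values, 1.0), np.nan + 1j * np.nan)
    return Spectrum(omega=omega, values=vals, n_windows=S_xx.n_windows,
                    pair=("eta", "eta"), se=None)


def naive_recover_no_refractory(
    chi: Susceptibility, S_xv: Spectrum, S_xx: Spectrum,
    v_T: float, v_R: float,
    convention: Convention = AUDITED_CONVENTION,
) -> Spectrum:
    """Noise-spectrum recovery ignoring the refractory period entirely.

    The exact relation of the non-refractory leaky model,
    ``S_eta_eta = [(1+i*omega) S_xv + (v_T - v_R) S_xx]/chi``; coincides
    with :func:`recover_noise_spectrum` in the limit ``tau_ref -> 0``.
    """
    omega = S_xv.omega
    sxv = convention.c_s(S_xv.values)
    num = convention.sign * ((1.0 + 1j * omega) * sxv + (v_T - v_R) * S_xx.values.real)
    ok = _chi_division_mask(chi)
    vals = np.where(ok, num / np.where(ok, chi.values, 1.0), np.nan + 1j * np.nan)
    return Spectrum(omega=omega, values=vals, n_windows=S_xx.n_windows,
                    pair=("eta", "eta"), se=None)


def naive_recover_white_form(
    chi: Susceptibility, S_xv: Spectrum, S_xx: Spectrum,
    FI: RefractoryCurrentFT,
    convention: Convention = AUDITED_CONVENTION,
) -> Spectrum:
    """Noise-spectrum recovery from the white-noise FRR applied ad hoc.

    Keeps the refractory current but drops the triple-correlation term:
    ``S_eta_eta = [(1+i*omega) S_xv + FI S_xx]/chi``.  Differs from
    :func:`recover_noise_spectrum` exactly by
    ``<eta>_ref B_tilde S_xx / chi``.
    """
    omega = S_xv.omega
    sxv = convention.c_s(S_xv.values)
    fi = convention.c_f(np.interp(omega, FI.omega_grid, FI.values.real)
                        + 1j * np.interp(omega, FI.omega_grid, FI.values.imag))
    num = convention.sign * ((1.0 + 1j * omega) * sxv + fi * S_xx.values.real)
    ok = _chi_division_mask(chi)
    vals = np.where(ok, num / np.where(ok, chi.values, 1.0), np.nan + 1j * np.nan)
    return Spectrum(omega=omega, values=vals, n_windows=S_xx.n_windows,
                    pair=("eta", "eta"), se=None)


def frr_colored_sxv(
    chi: Susceptibility, noise: NoiseSpec, S_xx: Spectrum,
    FI: RefractoryCurrentFT, eta_ref_mean: float,
    convention: Convention = AUDITED_CONVENTION,
) -> Spectrum:
    """Predict the cross-spectrum ``S_xv`` under colored noise.

    ``S_xv = [chi S_eta_eta - FI S_xx - <eta>_ref B_tilde S_xx]/(1+i*omega)``
    in the audited orientation; reduces to the white-noise inversion when
    ``<eta>_ref = 0`` and the noise spectrum is flat.
    """
    omega = S_xx.omega
    tau_ref = FI.shape.tau_ref
    fi = convention.c_f(np.interp(omega, FI.omega_grid, FI.values.real)
                        + 1j * np.interp(omega, FI.omega_grid, FI.values.imag))
    bt = convention.c_f(np.asarray(boxcar_ft(tau_ref, omega)))
    oriented = (chi.values * noise.spectrum(omega) / convention.sign
                - (fi + eta_ref_mean * bt) * S_xx.values.real) / (1.0 + 1j * omega)
    return Spectrum(omega=omega, values=convention.c_s(oriented),
                    n_windows=S_xx.n_windows, pair=("x", "v"), se=None)


def general_relation_residual(
    chi_measured: Susceptibility, S_xv: Spectrum, S_xfv: Spectrum | None,
    S_xx: Spectrum, FI: RefractoryCurrentFT, triple: TripleTerm,
    noise: NoiseSpec,
    convention: Convention = AUDITED_CONVENTION,
) -> np.ndarray:
    """Residual of the pre-approximation relation with the empirical triple.

    ``chi - [i w S_xv - S_xf(v) + FI S_xx + T(w)]/S_eta_eta`` should be
    statistically zero for any Gaussian noise; the empirical triple term
    inherits the kernel orientation of the analytic transforms.
    """
    omega = S_xv.omega
    num = _numerator_white(S_xv, S_xfv, S_xx, FI, convention)
    num = num + convention.sign * convention.c_f(triple.values)
    return chi_measured.values - num / noise.spectrum(omega)


# ---------------------------------------------------------------------------
# convention audit


@dataclass
class AuditResult:
    best: Convention
    errors: dict[tuple[int, bool, bool], float]
    margin: float

    @property
    def unique(self) -> bool:
        return self.margin > 1.5


def audit_conventions(
    seed: int = 0,
    mu: float = 0.8, D: float = 0.1, tau_ref: float = 0.3,
    n_windows: int = 192, window_steps: int = 2**13, dt: float = 1e-3,
    n_windows_probe: int = 1024,
) -> AuditResult:
    """Select the orientation convention on a small white-noise run.

    Evaluates every candidate combination of overall sign, ``FI``
    conjugation and ``S_xv`` conjugation against a probe-measured
    susceptibility; the exactness of the white-noise relation makes the
    correct combination stand out by an order of magnitude.  A deliberately
    large ``tau_ref`` is used so that wrong refractory orientations are
    maximally penalized.
    """
    from .response import default_probe, estimate_susceptibility_signal

    shape = SpikeShape.clamp(tau_ref)
    model = ModelSpec(mu=mu, shape=shape)
    noise = NoiseSpec.white(D)
    from .response import accumulate_ensemble

    cfg = SimConfig(dt=dt, window_steps=window_steps, n_windows=n_windows, seed=seed)
    acc = accumulate_ensemble(model, noise, None, cfg,
                              pairs=[("x", "v"), ("x", "x")])
    S_xv, S_xx = acc.spectrum(("x", "v")), acc.spectrum(("x", "x"))
    probe_cfg = SimConfig(dt=dt, window_steps=window_steps,
                          n_windows=n_windows_probe, seed=seed + 1)
    chi = estimate_susceptibility_signal(model, noise, default_probe(), probe_cfg)
    FI = refractory_current_ft(shape, model, S_xv.omega)
    lo, hi = default_band(acc.r0)
    errors: dict[tuple[int, bool, bool], float] = {}
    for sign in (1, -1):
        for conj_fi in (False, True):
            for conj_sxv in (False, True):
                conv = Convention(sign=sign, conj_fi=conj_fi, conj_sxv=conj_sxv)
                rep = frr_white_chi(S_xv, None, S_xx, FI, D, measured=chi,
                                    convention=conv, band=(lo, hi))
                errors[(sign, conj_fi, conj_sxv)] = rep.band_median_rel_err
    ranked = sorted(errors.items(), key=lambda kv: kv[1])
    (sign, conj_fi, conj_sxv), best_err = ranked[0]
    margin = ranked[1][1] / best_err if best_err > 0 else float("inf")
    return AuditResult(best=Convention(sign=sign, conj_fi=conj_fi, conj_sxv=conj_sxv),
                       errors=errors, margin=margin)
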