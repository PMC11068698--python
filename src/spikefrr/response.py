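"""Independent measurement of rate, ISI statistics and susceptibility.

Two estimators of the susceptibility ``chi_x(omega)`` of the firing rate
are provided, serving as ground truth against which the fluctuation-
response predictions are tested:

``signal_probe``
    Drive the neuron with a weak broadband Gaussian signal ``epsilon*s(t)``
    (flat spectrum up to a cutoff well above the firing rate) and regress
    the spike train on the signal: ``chi = S_sx / (epsilon * S_ss)``.
``furutsu_novikov``
    For Gaussian driving noise, the noise-output cross-spectrum of a purely
    spontaneous run obeys ``S_eta_x = chi * S_eta_eta``, so the
    susceptibility can be read off without any stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .simulate import (ModelSpec, NoiseSpec, SignalSpec, SimConfig, SimOutput,
                       simulate_if)
from .spectra import SpectrumAccumulator


@dataclass
class ISIStats:
    r0: float
    r0_se: float
    mean_isi: float
    mean_isi_se: float
    cv: float
    n_spikes: int
    isis: np.ndarray


def isi_statistics(out: SimOutput) -> ISIStats:
    """Firing rate, mean interspike interval and CV with standard errors."""
    t = out.spike_times
    if t.size < 2:
        return ISIStats(r0=t.size / out.duration, r0_se=float("nan"),
                        mean_isi=float("nan"), mean_isi_se=float("nan"),
                        cv=float("nan"), n_spikes=t.size, isis=np.empty(0))
    isis = np.diff(t)
    mean = float(isis.mean())
    sd = float(isis.std(ddof=1))
    n = isis.size
    r0 = t.size / out.duration
    return ISIStats(
        r0=r0, r0_se=r0 * (sd / mean) / math.sqrt(n),
        mean_isi=mean, mean_isi_se=sd / math.sqrt(n),
        cv=sd / mean, n_spikes=t.size, isis=isis,
    )


@dataclass
class Susceptibility:
    """Complex firing-rate susceptibility on the positive-omega grid."""

    omega: np.ndarray
    values: np.ndarray
    se: np.ndarray
    method: str
    mask: np.ndarray
    epsilon_used: float | None = None
    linearity: float | None = None

    def band(self, lo: float, hi: float) -> np.ndarray:
        return (self.omega >= lo) & (self.omega <= hi) & self.mask


def accumulate_ensemble(
    model: ModelSpec, noise: NoiseSpec, signal: SignalSpec | None,
    config: SimConfig, pairs: list[tuple[str, str]],
    chunk_windows: int = 64,
    callback=None,
) -> SpectrumAccumulator:
    """Window-averaged spectra over a long run simulated in chunks.

    Chunks continue the voltage from the previous chunk's endpoint and use
    independent child streams of ``config.seed``; burn-in is discarded
    before the first chunk only.  ``callback(out)`` is invoked per chunk
    (used e.g. to collect triple-correlation estimates).
    """
    acc = SpectrumAccumulator(pairs, config.window_steps, config.dt)
    remaining = config.n_windows
    n_chunks = math.ceil(remaining / chunk_windows)
    children = np.random.SeedSequence(config.seed).spawn(n_chunks)
    v0 = None
    for i in range(n_chunks):
        nw = min(chunk_windows, remaining)
        cfg = replace(config, n_windows=nw, burn_in=None if i == 0 else 0.0)
        out = simulate_if(model, noise, signal, cfg, v0=v0,
                          rng=np.random.default_rng(children[i]))
        acc.add(out)
        if callback is not None:
            callback(out)
        v0 = float(out.v[-1])
        remaining -= nw
    return acc


def default_probe(level: float = 1.0, cutoff: float = 30.0,
                  epsilon: float = 0.2) -> SignalSpec:
    """Broadband probe defaults: flat up to ``cutoff`` (well above typical
    firing rates here), weak enough for linear response at the default
    noise levels."""
    return SignalSpec.broadband(epsilon=epsilon, level=level, cutoff=cutoff)


def estimate_susceptibility_signal(
    model: ModelSpec, noise: NoiseSpec, probe: SignalSpec,
    config: SimConfig, chunk_windows: int = 64,
    linearity_check: bool = False,
) -> Susceptibility:
    """Probe-based susceptibility ``chi = S_sx / (epsilon * S_ss)``.

    Frequencies without probe support (above the cutoff) are masked.  With
    ``linearity_check`` an equal-size run at ``epsilon/2`` is added and the
    band-median relative change stored as metadata (noise-limited unless
    the runs are long).
    """
    if probe.epsilon <= 0 or probe.kind != "broadband":
        raise ValueError("probe must be a broadband signal with epsilon > 0")
    acc = accumulate_ensemble(model, noise, probe, config,
                              pairs=[("s", "x"), ("s", "s"), ("x", "x")],
                              chunk_windows=chunk_windows)
    chi = _chi_from_probe_acc(acc, probe)
    if linearity_check:
        half = replace(probe, epsilon=probe.epsilon / 2)
        cfg2 = replace(config, seed=config.seed + 1)
        acc2 = accumulate_ensemble(model, noise, half, cfg2,
                                   pairs=[("s", "x"), ("s", "s"), ("x", "x")],
                                   chunk_windows=chunk_windows)
        chi2 = _chi_from_probe_acc(acc2, half)
        m = chi.mask & (np.abs(chi.values) > 0)
        rel = np.abs(chi2.values[m] - chi.values[m]) / np.abs(chi.values[m])
        chi.linearity = float(np.median(rel))
    return chi


def _chi_from_probe_acc(acc: SpectrumAccumulator, probe: SignalSpec) -> Susceptibility:
    S_sx = acc.spectrum(("s", "x"))
    S_ss = acc.spectrum(("s", "s"))
    S_xx = acc.spectrum(("x", "x"))
    eps = probe.epsilon
    support = S_ss.values.real > 0.1 * probe.level
    vals = np.zeros(S_sx.values.shape, complex)
    vals[support] = S_sx.values[support] / (eps * S_ss.values.real[support])
    # regression-noise error: residual rate fluctuations around the probe
    resid = np.maximum(S_xx.values.real - eps**2 * np.abs(vals) ** 2 * S_ss.values.real, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = resid / (eps**2 * S_ss.values.real * acc.n_windows)
    se_part = np.where(support, np.sqrt(var / 2.0), np.inf)
    se = np.empty(se_part.shape, complex)
    se.real = se_part
    se.imag = se_part
    return Susceptibility(
        omega=S_sx.omega, values=np.where(support, vals, 0.0),
        se=se, method="signal_probe",
        mask=support, epsilon_used=eps,
    )


def estimate_susceptibility_fn(
    spontaneous, noise: NoiseSpec,
) -> Susceptibility:
    """Furutsu-Novikov susceptibility ``chi = S_eta_x / S_eta_eta``.

    ``spontaneous`` is a :class:`SpectrumAccumulator` holding the
    ``("eta", "x")`` pair (or a SimOutput from an unstimulated run).  The
    denominator is the analytic noise spectrum: the constant ``2 D`` for
    white noise, the Lorentzian for Ornstein-Uhlenbeck noise.
    """
    if isinstance(spontaneous, SpectrumAccumulator):
        S_ex = spontaneous.spectrum(("eta", "x"))
    else:
        from .spectra import spectra_from_output

        S_ex = spectra_from_output(spontaneous, [("eta", "x")])[("eta", "x")]
    S_ee = noise.spectrum(S_ex.omega)
    vals = S_ex.values / S_ee
    se = (S_ex.se.real + 1j * S_ex.se.imag) / S_ee
    return Susceptibility(
        omega=S_ex.omega, values=vals, se=se, method="furutsu_novikov",
        mask=np.ones(vals.shape, bool),
    )
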