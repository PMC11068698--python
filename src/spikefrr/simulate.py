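"""Stochastic simulation of integrate-and-fire models with a refractory state.

The model integrates the membrane voltage with an Euler-Maruyama step

    v <- v + dt * ( f(v) + eta(t) + epsilon * s(t) )

outside the refractory state.  The first grid time at which ``v >= v_T`` is
recorded as a spike; for the following ``tau_ref`` the voltage follows the
attached spike-shape table (noise and signal do not influence the voltage
there, although both processes keep evolving), and at ``t_i + tau_ref``
integration resumes from exactly ``v_R``.

The driving noise ``eta`` is either white Gaussian with intensity ``D``
(discretized as ``sqrt(2 D / dt) * g_k`` so that its spectrum is flat at
``2 D``) or an Ornstein-Uhlenbeck process with variance ``sigma2`` and
correlation time ``tau_c``, generated with the exact one-step update so that
the Lorentzian spectrum holds at any step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

from .shapes import Impulse, SpikeShape, snap_to_grid


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class ModelSpec:
    """Drift, threshold/reset and attached spike shape.

    ``mu`` parametrizes the leaky drift ``f(v) = mu - v``; a ``drift_fn``
    callable overrides it for non-leaky models (slow python path, intended
    for small validation runs).
    """

    mu: float
    shape: SpikeShape
    v_T: float = 1.0
    v_R: float = 0.0
    drift_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.v_R >= self.v_T:
            raise ValueError("require v_R < v_T")
        if self.shape.v_T != self.v_T or self.shape.v_R != self.v_R:
            raise ValueError("spike shape boundary values must match the model")

    @property
    def tau_ref(self) -> float:
        return self.shape.tau_ref

    @property
    def is_lif(self) -> bool:
        return self.drift_fn is None

    def f(self, v):
        return self.drift_fn(v) if self.drift_fn is not None else self.mu - v


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian drive: ``white(D)`` or ``ou(sigma2, tau_c)``."""

    kind: str
    D: float | None = None
    sigma2: float | None = None
    tau_c: float | None = None

    @classmethod
    def white(cls, D: float) -> "NoiseSpec":
        if D <= 0:
            raise ValueError("noise intensity D must be positive")
        return cls(kind="white", D=D)

    @classmethod
    def ou(cls, sigma2: float, tau_c: float) -> "NoiseSpec":
        if sigma2 <= 0 or tau_c <= 0:
            raise ValueError("sigma2 and tau_c must be positive")
        return cls(kind="ou", sigma2=sigma2, tau_c=tau_c)

    def spectrum(self, omega) -> np.ndarray:
        """Analytic two-sided power spectrum of the drive."""
        w = np.asarray(omega, float)
        if self.kind == "white":
            return np.full(w.shape, 2.0 * self.D)
        return 2.0 * self.sigma2 * self.tau_c / (1.0 + (self.tau_c * w) ** 2)


@dataclass(frozen=True)
class SignalSpec:
    """Weak probe signal ``epsilon * s(t)``.

    ``broadband`` draws, per analysis window, a Gaussian signal that is
    exactly band-limited white in the discrete Fourier basis: spectral
    height ``level`` for ``0 < omega <= cutoff`` and zero above.
    """

    epsilon: float = 0.0
    kind: str = "none"
    level: float | None = None
    cutoff: float | None = None
    omega0: float | None = None
    amplitude: float | None = None

    @classmethod
    def none(cls) -> "SignalSpec":
        return cls()

    @classmethod
    def broadband(cls, epsilon: float, level: float, cutoff: float) -> "SignalSpec":
        if epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        return cls(epsilon=epsilon, kind="broadband", level=level, cutoff=cutoff)

    @classmethod
    def sinusoid(cls, epsilon: float, omega0: float, amplitude: float = 1.0) -> "SignalSpec":
        return cls(epsilon=epsilon, kind="sinusoid", omega0=omega0, amplitude=amplitude)

    @property
    def linear_regime_advisory(self) -> bool:
        """Flag raised when epsilon is large for a linear-response probe."""
        return self.epsilon > 0.2


@dataclass(frozen=True)
class SimConfig:
    """Numerical run layout: step, window length, window count, burn-in."""

    dt: float = 1e-3
    window_steps: int = 2**14
    n_windows: int = 64
    burn_in: float | None = None
    seed: int = 0

    @property
    def T_window(self) -> float:
        return self.window_steps * self.dt

    def omega_grid(self) -> np.ndarray:
        """Positive angular frequencies ``2*pi*k/T_window``, k = 1..N/2-1."""
        k = np.arange(1, self.window_steps // 2)
        return 2.0 * np.pi * k / self.T_window


@dataclass
class SimOutput:
    """Sampled traces and spike times of one simulation run (burn-in cut)."""

    dt: float
    window_steps: int
    n_windows: int
    v: np.ndarray
    eta: np.ndarray
    s: np.ndarray
    ref_indicator: np.ndarray
    spike_indices: np.ndarray  # sample indices into the trace arrays
    model: ModelSpec
    noise: NoiseSpec
    signal: SignalSpec
    zero_spikes: bool = False

    @property
    def spike_times(self) -> np.ndarray:
        return self.spike_indices * self.dt

    @property
    def duration(self) -> float:
        return self.v.size * self.dt

    @property
    def rate(self) -> float:
        return self.spike_indices.size / self.duration

    def windows(self, name: str) -> np.ndarray:
        """Series reshaped to (n_windows, window_steps).

        Names: ``v``, ``eta``, ``s``, ``x`` (binned spike train, counts/dt),
        ``fv`` (drift evaluated on the voltage trace).
        """
        n = self.n_windows * self.window_steps
        if name == "x":
            arr = self.binned_spike_train()
        elif name == "fv":
            arr = np.asarray(self.model.f(self.v), float)
        else:
            arr = getattr(self, name)
        return arr[:n].reshape(self.n_windows, self.window_steps)

    def binned_spike_train(self) -> np.ndarray:
        """Delta-train density: spike counts per bin divided by dt."""
        x = np.zeros(self.v.size)
        np.add.at(x, self.spike_indices, 1.0 / self.dt)
        return x


# ---------------------------------------------------------------------------
# noise / signal generation


def generate_ou_noise(
    sigma2: float, tau_c: float, dt: float, n_steps: int,
    rng: np.random.Generator | int | None = 0, eta0: float | None = None,
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path via the exact update.

    ``eta[k+1] = a*eta[k] + sqrt(sigma2*(1-a^2))*g[k]`` with
    ``a = exp(-dt/tau_c)``; the initial value is drawn from the stationary
    normal unless ``eta0`` is given.
    """
    if sigma2 <= 0 or tau_c <= 0 or dt <= 0:
        raise ValueError("sigma2, tau_c and dt must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a = math.exp(-dt / tau_c)
    g = rng.standard_normal(n_steps)
    if eta0 is None:
        g[0] *= math.sqrt(sigma2)
    else:
        g[0] = eta0
    sig = math.sqrt(sigma2 * (1.0 - a * a))
    return _ou_filter(g, a, sig)


@njit(cache=True)
def _ou_filter(g, a, sig):
    out = np.empty_like(g)
    out[0] = g[0]
    for k in range(1, g.size):
        out[k] = a * out[k - 1] + sig * g[k]
    return out


def _broadband_signal(
    level: float, cutoff: float, dt: float, window_steps: int,
    n_windows: int, rng: np.random.Generator,
) -> np.ndarray:
    """Per-window band-limited Gaussian white signal with flat height."""
    N = window_steps
    T = N * dt
    k_c = min(int(cutoff * T / (2.0 * np.pi)), N // 2 - 1)
    if k_c < 1:
        raise ValueError("cutoff below the frequency resolution of a window")
    sigma_z = math.sqrt(level * N / dt)
    z = np.zeros((n_windows, N // 2 + 1), complex)
    re = rng.standard_normal((n_windows, k_c))
    im = rng.standard_normal((n_windows, k_c))
    z[:, 1 : k_c + 1] = (re + 1j * im) * (sigma_z / math.sqrt(2.0))
    return np.fft.irfft(z, n=N, axis=1).ravel()


def _make_signal(signal: SignalSpec, dt: float, window_steps: int,
                 n_windows: int, rng: np.random.Generator) -> np.ndarray:
    n = window_steps * n_windows
    if signal.kind == "none" or signal.epsilon == 0.0:
        return np.zeros(n)
    if signal.kind == "broadband":
        return _broadband_signal(signal.level, signal.cutoff, dt,
                                 window_steps, n_windows, rng)
    if signal.kind == "sinusoid":
        t = np.arange(n) * dt
        return signal.amplitude * np.cos(signal.omega0 * t)
    raise ValueError(f"unknown signal kind {signal.kind!r}")


# ---------------------------------------------------------------------------
# core integrators


@njit(cache=True)
def _lif_core(v0, mu, v_T, v_R, dt, drive, n_ref, table, v_out, ref_out, spikes):
    """Euler-Maruyama LIF loop with scheduled refractory playback.

    Returns (n_spikes, error_flag); error_flag = 1 on non-finite voltage.
    """
    n = drive.shape[0]
    v_out[0] = v0
    k = 0
    nspk = 0
    while k < n - 1:
        vn = v_out[k] + dt * ((mu - v_out[k]) + drive[k])
        if not np.isfinite(vn):
            return nspk, 1
        if vn >= v_T:
            i = k + 1
            if nspk < spikes.size:
                spikes[nspk] = i
            nspk += 1
            for j in range(n_ref):
                if i + j >= n:
                    break
                v_out[i + j] = table[j]
                ref_out[i + j] = 1
            if i + n_ref < n:
                v_out[i + n_ref] = v_R
            k = i + n_ref
        else:
            v_out[k + 1] = vn
            k += 1
    return nspk, 0


def _generic_core(v0, f, v_T, v_R, dt, drive, n_ref, table, v_out, ref_out):
    """Python twin of :func:`_lif_core` for arbitrary drift functions."""
    n = drive.shape[0]
    v_out[0] = v0
    k = 0
    spikes = []
    while k < n - 1:
        vn = v_out[k] + dt * (f(v_out[k]) + drive[k])
        if not np.isfinite(vn):
            raise FloatingPointError(f"voltage became non-finite at step {k}")
        if vn >= v_T:
            i = k + 1
            spikes.append(i)
            stop = min(i + n_ref, n)
            m = stop - i
            v_out[i:stop] = table[:m]
            ref_out[i:stop] = 1
            if i + n_ref < n:
                v_out[i + n_ref] = v_R
            k = i + n_ref
        else:
            v_out[k + 1] = vn
            k += 1
    return np.array(spikes, dtype=np.int64), 0


def default_burn_in(model: ModelSpec, noise: NoiseSpec) -> float:
    """Ten times the slowest characteristic time (membrane, noise, ISI)."""
    scales = [1.0, model.tau_ref]
    if noise.kind == "ou":
        scales.append(noise.tau_c)
    if model.is_lif and model.mu > model.v_T:
        scales.append(model.tau_ref + math.log(
            (model.mu - model.v_R) / (model.mu - model.v_T)))
    return 10.0 * max(scales)


def simulate_if(
    model: ModelSpec,
    noise: NoiseSpec,
    signal: SignalSpec | None = None,
    config: SimConfig | None = None,
    v0: float | None = None,
    rng: np.random.Generator | None = None,
) -> SimOutput:
    """Simulate the IF model and return traces, spike times and indicators.

    Burn-in (rounded up to whole windows) is simulated and discarded before
    the ``n_windows`` analysis windows are emitted.  Pass an explicit ``rng``
    (and ``v0``) to continue a stream across chunked calls; otherwise a
    generator is derived from ``config.seed``.
    """
    signal = signal or SignalSpec.none()
    config = config or SimConfig()
    dt = config.dt
    tau_ref = snap_to_grid(model.tau_ref, dt)
    n_ref = int(round(tau_ref / dt))
    table = model.shape.sample(dt)[:n_ref] if n_ref else np.empty(0)

    burn = config.burn_in if config.burn_in is not None else default_burn_in(model, noise)
    burn_windows = int(math.ceil(burn / config.T_window - 1e-12)) if burn > 0 else 0
    total_windows = burn_windows + config.n_windows
    n = total_windows * config.window_steps

    if rng is None:
        ss = np.random.SeedSequence(config.seed)
        rng_eta, rng_sig = [np.random.default_rng(c) for c in ss.spawn(2)]
    else:
        rng_eta = rng_sig = rng

    if noise.kind == "white":
        eta = rng_eta.standard_normal(n) * math.sqrt(2.0 * noise.D / dt)
    else:
        eta = generate_ou_noise(noise.sigma2, noise.tau_c, dt, n, rng_eta)
    s = _make_signal(signal, dt, config.window_steps, total_windows, rng_sig)
    drive = eta + signal.epsilon * s if signal.epsilon else eta

    v = np.empty(n)
    ref = np.zeros(n, dtype=np.uint8)
    v_start = model.v_R if v0 is None else v0

    if model.is_lif:
        buf = np.empty(n // (n_ref + 1) + 2, dtype=np.int64)
        nspk, err = _lif_core(v_start, model.mu, model.v_T, model.v_R, dt,
                              drive, n_ref, table, v, ref, buf)
        if err:
            raise FloatingPointError("voltage became non-finite during integration")
        spikes = buf[:nspk].copy()
    else:
        spikes, _ = _generic_core(v_start, model.f, model.v_T, model.v_R, dt,
                                  drive, n_ref, table, v, ref)

    cut = burn_windows * config.window_steps
    spikes = spikes[spikes >= cut] - cut
    return SimOutput(
        dt=dt, window_steps=config.window_steps, n_windows=config.n_windows,
        v=v[cut:], eta=eta[cut:], s=s[cut:], ref_indicator=ref[cut:],
        spike_indices=spikes, model=model, noise=noise, signal=signal,
        zero_spikes=(spikes.size == 0),
    )


# ---------------------------------------------------------------------------
# effective traces


@dataclass
class EffectiveTraces:
    """Decomposition of the formal voltage dynamics.

    ``eta_eff`` is the noise gated off inside refractory windows;
    ``i_eff`` is the smooth part of the spike-shape enforcing current
    ``sum_i [dv_spike/dt - f(v_spike)](t - t_i)``; any derivative boundary
    impulses are listed symbolically in ``impulses``.
    """

    eta_eff: np.ndarray
    i_eff: np.ndarray
    impulses: list[Impulse]


def effective_traces(out: SimOutput, model: ModelSpec | None = None) -> EffectiveTraces:
    model = model or out.model
    if model.shape is not out.model.shape and model.shape != out.model.shape:
        raise ValueError("model/shape does not match the simulation output")
    eta_eff = out.eta * (1.0 - out.ref_indicator)
    n_ref = int(round(model.tau_ref / out.dt))
    i_eff = np.zeros_like(out.v)
    impulses: list[Impulse] = []
    if n_ref:
        tau = np.arange(n_ref) * out.dt
        shape = model.shape
        vs = np.asarray(shape.value(tau), float)
        if shape.kind == "clamp":
            dvs = np.zeros(n_ref)
        else:
            dvs = np.asarray(shape.derivative(tau), float)
        seg = dvs - np.asarray(model.f(vs), float)
        for idx in out.spike_indices:
            stop = min(idx + n_ref, i_eff.size)
            i_eff[idx:stop] += seg[: stop - idx]
            if shape.impulse is not None:
                imp = shape.impulse
                impulses.append(Impulse(idx * out.dt + imp.time, imp.weight))
    return EffectiveTraces(eta_eff=eta_eff, i_eff=i_eff, impulses=impulses)
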