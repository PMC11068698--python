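"""Spectral estimation for spike trains, voltage traces and noise.

Conventions (package-wide):

* Fourier transform with kernel ``exp(+i*omega*t)``:
  ``tilde_a(omega) = dt * sum_n a_n exp(+i*omega*t_n)``.
* Cross-spectrum orientation ``S_ab = <tilde_b * conj(tilde_a)> / T``,
  i.e. the transform of the correlation function
  ``C_ab(tau) = <a(t) b(t+tau)>``.  Swapping the pair conjugates the
  estimate exactly.
* Window means are subtracted before transforming (this removes the DC
  delta carried by the firing rate and makes the estimates covariances).
* Estimates are averaged over non-overlapping windows of length
  ``T = window_steps * dt``; no taper by default (long boxcar windows), a
  Hann taper is available as an option.

Only positive frequencies ``omega_k = 2*pi*k/T`` for ``k = 1..N/2-1`` are
stored; negative frequencies follow from conjugate symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simulate import SimOutput


@dataclass
class BinnedSpikeTrain:
    """Delta spike train on a grid: counts per bin divided by the bin width."""

    dt: float
    values: np.ndarray
    r0: float


def bin_spike_train(spike_times: np.ndarray, dt: float, T_window: float) -> BinnedSpikeTrain:
    spike_times = np.asarray(spike_times, float)
    if spike_times.size and (spike_times.min() < 0 or spike_times.max() >= T_window):
        raise ValueError("spike times must lie inside [0, T_window)")
    n = int(round(T_window / dt))
    values = np.zeros(n)
    idx = np.floor(spike_times / dt).astype(int)
    np.add.at(values, idx, 1.0 / dt)
    return BinnedSpikeTrain(dt=dt, values=values, r0=spike_times.size / T_window)


@dataclass
class Spectrum:
    """Window-averaged (cross-)spectral estimate on the positive-omega grid.

    ``se`` stores the standard error of the real part in its real component
    and of the imaginary part in its imaginary component.
    """

    omega: np.ndarray
    values: np.ndarray
    n_windows: int
    pair: tuple[str, str]
    se: np.ndarray | None = None
    convention: str = "S_ab = <tilde_b conj(tilde_a)>/T, kernel exp(+i w t)"

    def band(self, lo: float, hi: float) -> np.ndarray:
        return (self.omega >= lo) & (self.omega <= hi)


def _as_windows(a, window_steps: int) -> np.ndarray:
    a = np.asarray(a, float)
    if a.ndim == 1:
        n_w = a.size // window_steps
        a = a[: n_w * window_steps].reshape(n_w, window_steps)
    return a


def tilde_ft(windows: np.ndarray, dt: float, demean: bool = True,
             taper: str | None = None) -> np.ndarray:
    """Per-window finite-time transform with the ``exp(+i*omega*t)`` kernel."""
    w = np.asarray(windows, float)
    if demean:
        w = w - w.mean(axis=-1, keepdims=True)
    if taper == "hann":
        win = np.hanning(w.shape[-1])
        w = w * (win / np.sqrt(np.mean(win**2)))
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    return dt * np.conj(np.fft.rfft(w, axis=-1))


def estimate_spectrum(
    a, b, dt: float, window_steps: int | None = None,
    pair: tuple[str, str] = ("a", "b"), demean: bool = True,
    taper: str | None = None,
) -> Spectrum:
    """Cross-spectrum ``S_ab`` averaged over windows, with standard errors.

    ``a`` and ``b`` are equal-shape (n_windows, N) arrays, or 1-d traces cut
    into windows of ``window_steps`` samples.  ``n_windows >= 2`` is required
    for a standard error.
    """
    same = a is b
    if window_steps is not None:
        a = _as_windows(a, window_steps)
        b = a if same else _as_windows(b, window_steps)
    a = np.atleast_2d(np.asarray(a, float))
    b = a if same else np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError(f"window shapes differ: {a.shape} vs {b.shape}")
    n_w, N = a.shape
    if n_w < 2:
        raise ValueError("need at least 2 windows")
    T = N * dt
    ta = tilde_ft(a, dt, demean, taper)
    tb = tilde_ft(b, dt, demean, taper) if b is not a else ta
    prod = (tb * np.conj(ta))[:, 1 : N // 2] / T
    vals = prod.mean(axis=0)
    se = (prod.real.std(axis=0, ddof=1) + 1j * prod.imag.std(axis=0, ddof=1)) / np.sqrt(n_w)
    omega = 2.0 * np.pi * np.arange(1, N // 2) / T
    if same or pair[0] == pair[1]:
        vals = vals.real + 0j
    return Spectrum(omega=omega, values=vals, n_windows=n_w, pair=pair, se=se)


def spectra_from_output(out: SimOutput, pairs: list[tuple[str, str]],
                        taper: str | None = None) -> dict[tuple[str, str], Spectrum]:
    """Estimate several cross-spectra from one simulation output.

    Series names: ``x`` (binned spike train), ``v``, ``eta``, ``s``, ``fv``.
    """
    cache: dict[str, np.ndarray] = {}

    def get(name):
        if name not in cache:
            cache[name] = out.windows(name)
        return cache[name]

    return {
        (na, nb): estimate_spectrum(get(na), get(nb), out.dt, pair=(na, nb), taper=taper)
        for na, nb in pairs
    }


class SpectrumAccumulator:
    """Streaming window-averaged spectra over chunked simulations.

    Accumulates per-window cross-periodograms (sum and sum of squares of the
    real/imag parts) for the requested pairs, plus the scalar stationary
    statistics needed by the fluctuation-response formulas (firing rate,
    mean voltage, mean drift, refractory-conditioned noise mean).
    """

    def __init__(self, pairs: list[tuple[str, str]], window_steps: int, dt: float):
        self.pairs = list(pairs)
        self.N = window_steps
        self.dt = dt
        m = window_steps // 2 - 1
        self._sum = {p: np.zeros(m, complex) for p in self.pairs}
        self._sq = {p: np.zeros(m, complex) for p in self.pairs}  # re/im separately
        self.n_windows = 0
        self.spike_count = 0
        self.duration = 0.0
        self._v_sum = 0.0
        self._fv_sum = 0.0
        self._n_samples = 0
        self._eta_ref_sum = 0.0
        self._eta_ref_n = 0
        self._spike_means: list[np.ndarray] = []
        # per-window scalar statistics for standard errors of the means
        self._fv_wsum = 0.0
        self._fv_wsq = 0.0
        self._ct_wsum = 0.0
        self._ct_wsq = 0.0

    def add(self, out: SimOutput) -> None:
        T = self.N * self.dt
        tf: dict[str, np.ndarray] = {}
        names = {n for p in self.pairs for n in p}
        for name in names:
            tf[name] = tilde_ft(out.windows(name), self.dt)
        for na, nb in self.pairs:
            prod = (tf[nb] * np.conj(tf[na]))[:, 1 : self.N // 2] / T
            self._sum[(na, nb)] += prod.sum(axis=0)
            self._sq[(na, nb)] += (prod.real**2).sum(axis=0) + 1j * (prod.imag**2).sum(axis=0)
        self.n_windows += out.n_windows
        self.spike_count += out.spike_indices.size
        self.duration += out.duration
        self._v_sum += float(out.v.sum())
        self._fv_sum += float(np.sum(out.model.f(out.v)))
        self._n_samples += out.v.size
        inref = out.ref_indicator.astype(bool)
        self._eta_ref_sum += float(out.eta[inref].sum())
        self._eta_ref_n += int(inref.sum())
        self._spike_means.append(_per_spike_eta_means(out))
        fv_w = np.asarray(out.model.f(out.v), float)[: out.n_windows * self.N]
        fv_w = fv_w.reshape(out.n_windows, self.N).mean(axis=1)
        self._fv_wsum += float(fv_w.sum())
        self._fv_wsq += float((fv_w**2).sum())
        counts = np.bincount(out.spike_indices // self.N, minlength=out.n_windows)
        counts = counts[: out.n_windows]
        self._ct_wsum += float(counts.sum())
        self._ct_wsq += float((counts.astype(float) ** 2).sum())

    def spectrum(self, pair: tuple[str, str]) -> Spectrum:
        n = self.n_windows
        mean = self._sum[pair] / n
        var_re = self._sq[pair].real / n - mean.real**2
        var_im = self._sq[pair].imag / n - mean.imag**2
        se = (np.sqrt(np.maximum(var_re, 0)) + 1j * np.sqrt(np.maximum(var_im, 0))) / np.sqrt(n)
        omega = 2.0 * np.pi * np.arange(1, self.N // 2) / (self.N * self.dt)
        vals = mean.real + 0j if pair[0] == pair[1] else mean
        return Spectrum(omega=omega, values=vals, n_windows=n, pair=pair, se=se)

    @property
    def r0(self) -> float:
        return self.spike_count / self.duration

    @property
    def mean_v(self) -> float:
        return self._v_sum / self._n_samples

    @property
    def mean_fv(self) -> float:
        return self._fv_sum / self._n_samples

    @property
    def mean_fv_se(self) -> float:
        """Standard error of the drift mean from window-to-window scatter."""
        n = self.n_windows
        m = self._fv_wsum / n
        var = max(self._fv_wsq / n - m * m, 0.0)
        return math.sqrt(var / n)

    @property
    def r0_se(self) -> float:
        n = self.n_windows
        m = self._ct_wsum / n
        var = max(self._ct_wsq / n - m * m, 0.0)
        return math.sqrt(var / n) / (self.N * self.dt)

    def eta_ref_mean(self) -> tuple[float, float]:
        """Pooled refractory-window noise mean and its standard error."""
        if self._eta_ref_n == 0:
            return float("nan"), float("nan")
        mean = self._eta_ref_sum / self._eta_ref_n
        per_spike = np.concatenate(self._spike_means) if self._spike_means else np.empty(0)
        if per_spike.size > 1:
            se = per_spike.std(ddof=1) / np.sqrt(per_spike.size)
        else:
            se = float("nan")
        return mean, se


def _per_spike_eta_means(out: SimOutput) -> np.ndarray:
    """Mean of eta over each complete refractory window (one value per spike)."""
    n_ref = int(round(out.model.tau_ref / out.dt))
    if n_ref == 0 or out.spike_indices.size == 0:
        return np.empty(0)
    idx = out.spike_indices[out.spike_indices + n_ref <= out.eta.size]
    if idx.size == 0:
        return np.empty(0)
    csum = np.concatenate([[0.0], np.cumsum(out.eta)])
    return (csum[idx + n_ref] - csum[idx]) / n_ref


def eta_ref_mean_empirical(ensemble) -> tuple[float, float]:
    """Average noise value inside refractory windows, with standard error.

    The standard error treats each spike's refractory window as one
    (approximately independent) observation, which is appropriate for
    correlated noise.  Accepts a SimOutput or a list of them.
    """
    outs = ensemble if isinstance(ensemble, (list, tuple)) else [ensemble]
    per_spike = np.concatenate([_per_spike_eta_means(o) for o in outs])
    if per_spike.size == 0:
        return float("nan"), float("nan")
    se = per_spike.std(ddof=1) / np.sqrt(per_spike.size) if per_spike.size > 1 else float("nan")
    return float(per_spike.mean()), float(se)


def smooth_decimate(spec: Spectrum, factor: int) -> Spectrum:
    """Frequency-smooth a fine-grid spectrum onto a ``factor``-coarser grid.

    A centered boxcar of ``factor`` adjacent fine bins is averaged around
    each coarse grid point (Welch-style frequency smoothing: adjacent bins
    of a long window are nearly independent estimates of a smooth curve, so
    the variance drops by ``factor`` at the cost of resolution).  The coarse
    grid coincides with the grid of windows ``factor`` times shorter.
    """
    if factor == 1:
        return spec
    vals = spec.values
    n = vals.size
    out, se_out, om = [], [], []
    for k in range(1, n // factor + 1):
        c = k * factor - 1
        a, b = max(0, c - factor // 2), min(n, c + factor // 2)
        out.append(vals[a:b].mean())
        if spec.se is not None:
            se_out.append((np.mean(spec.se.real[a:b]) + 1j * np.mean(spec.se.imag[a:b]))
                          / np.sqrt(b - a))
        om.append(spec.omega[c])
    return Spectrum(omega=np.array(om), values=np.array(out),
                    n_windows=spec.n_windows, pair=spec.pair,
                    se=np.array(se_out) if spec.se is not None else None,
                    convention=spec.convention)


@dataclass
class TripleTerm:
    """Estimate of the transformed refractory triple correlation.

    ``values`` approximates ``F_tau[ int_0^tau_ref dtau'
    <x(0) x(tau - tau') eta(tau)> ]`` on the positive-omega grid, the term
    that closes the general fluctuation-response relation before any
    white-noise or short-correlation-time simplification.
    """

    omega: np.ndarray
    values: np.ndarray
    se: np.ndarray
    n_windows: int


def triple_term(ensemble, tau_ref: float | None = None) -> TripleTerm:
    """Estimate the triple-correlation term from simulation output.

    For each lag ``tau' = j*dt`` up to ``tau_ref`` the product series
    ``y_j(t) = x(t - tau') * eta(t)`` is formed and its cross-spectrum with
    the spike train taken; the ``tau'`` integral is a trapezoid over lags.
    Window means of both factors are removed, which strips the stationary
    ``<x><x><eta>`` offsets into the (discarded) DC bin.
    """
    outs = ensemble if isinstance(ensemble, (list, tuple)) else [ensemble]
    first = outs[0]
    dt = first.dt
    N = first.window_steps
    T = N * dt
    n_ref = int(round((tau_ref if tau_ref is not None else first.model.tau_ref) / dt))
    m = N // 2 - 1
    total = np.zeros(m, complex)
    total_sq = np.zeros(m, complex)
    n_w = 0
    for out in outs:
        n = out.n_windows * N
        x = out.binned_spike_train()[:n]
        eta = out.eta[:n]
        tx = tilde_ft(x.reshape(out.n_windows, N), dt)
        acc = np.zeros((out.n_windows, m), complex)
        for j in range(n_ref + 1):
            xs = np.empty_like(x)
            if j:
                xs[:j] = 0.0
                xs[j:] = x[:-j]
            else:
                xs[:] = x
            y = (xs * eta).reshape(out.n_windows, N)
            ty = tilde_ft(y, dt)
            prod = (ty * np.conj(tx))[:, 1 : N // 2] / T
            w = 0.5 if j in (0, n_ref) else 1.0
            acc += w * dt * prod
        total += acc.sum(axis=0)
        total_sq += (acc.real**2).sum(axis=0) + 1j * (acc.imag**2).sum(axis=0)
        n_w += out.n_windows
    mean = total / n_w
    var_re = total_sq.real / n_w - mean.real**2
    var_im = total_sq.imag / n_w - mean.imag**2
    se = (np.sqrt(np.maximum(var_re, 0)) + 1j * np.sqrt(np.maximum(var_im, 0))) / np.sqrt(n_w)
    omega = 2.0 * np.pi * np.arange(1, N // 2) / T
    return TripleTerm(omega=omega, values=mean, se=se, n_windows=n_w)
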