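"""Stereotypical spike shapes and the refractory current they induce.

During the absolute refractory period of duration ``tau_ref`` the membrane
voltage of the integrate-and-fire model follows a prescribed waveform
``v_spike(t)`` that connects the threshold ``v_T`` (at ``t = 0``) to the
reset ``v_R`` (at ``t = tau_ref``).  Three families are supported:

``clamp``
    The voltage is held at the reset value for the whole refractory period,
    ``v_spike(t) = v_T - (v_T - v_R) * Theta(t)``.  Its time derivative is a
    Dirac impulse of weight ``v_R - v_T`` at the left edge, which this module
    represents symbolically (never as a large float).
``alpha``
    An alpha-type waveform ``v_spike(t) = kappa*(t + t0)*exp(-beta*t) -
    delta_v``.  The free parameters are ``kappa`` (rise rate) and ``delta_v``
    (undershoot offset); ``t0`` and ``beta`` are derived from the boundary
    conditions.
``tabulated``
    Arbitrary sampled waveform, linearly interpolated.

The module also provides the Fourier transform (kernel ``exp(+i*omega*t)``,
the package-wide convention) of the effective refractory input current

    I_ref_current(t) = B_tau_ref(t) * [f(v_spike(t)) - dv_spike/dt(t)],

the single-spike current that enforces the shape on top of the free drift
``f(v)``.  For a leaky integrator ``f(v) = mu - v`` this is the familiar
``B * [mu - v_spike - v_spike']``.  The impulse hidden in the clamp
derivative contributes its full weight, ``+(v_T - v_R)``, to the transform;
this sign is the one for which the white-noise fluctuation-response relation
closes exactly (see :mod:`spikefrr.frr` for the numerical audit).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np


class Impulse(NamedTuple):
    """A Dirac impulse ``weight * delta(t - time)`` recorded symbolically."""

    time: float
    weight: float


class ShapeParameterError(ValueError):
    """Raised when spike-shape parameters violate a boundary condition."""


def solve_alpha_params(
    kappa: float,
    delta_v: float,
    tau_ref: float,
    v_T: float = 1.0,
    v_R: float = 0.0,
) -> tuple[float, float]:
    """Solve the alpha-shape boundary conditions for ``(t0, beta)``.

    The waveform ``kappa*(t + t0)*exp(-beta*t) - delta_v`` must start at the
    threshold, ``v_spike(0) = v_T``, and end at the reset,
    ``v_spike(tau_ref) = v_R``.  The first condition gives
    ``t0 = (v_T + delta_v)/kappa``; the second then yields
    ``beta = log(kappa*(tau_ref + t0)/(v_R + delta_v)) / tau_ref``.

    Raises
    ------
    ShapeParameterError
        If the parameters cannot satisfy the boundary conditions
        (``kappa <= 0``, ``v_R + delta_v <= 0``, or the waveform cannot decay
        down to ``v_R`` at ``tau_ref``).
    """
    if tau_ref <= 0:
        raise ShapeParameterError(f"tau_ref must be positive, got {tau_ref}")
    if kappa <= 0:
        raise ShapeParameterError(f"kappa must be positive, got {kappa}")
    if v_R + delta_v <= 0:
        raise ShapeParameterError(
            f"need v_R + delta_v > 0 for the log to exist, got {v_R + delta_v}"
        )
    t0 = (v_T + delta_v) / kappa
    peak = kappa * (tau_ref + t0)
    if peak <= v_R + delta_v:
        raise ShapeParameterError(
            "shape cannot reach v_R at tau_ref: requires "
            f"kappa*(tau_ref + t0) = {peak:g} > v_R + delta_v = {v_R + delta_v:g}"
        )
    beta = math.log(peak / (v_R + delta_v)) / tau_ref
    return t0, beta


@dataclass(frozen=True)
class SpikeShape:
    """A stereotypical spike waveform on ``[0, tau_ref]``.

    Construct through :meth:`clamp`, :meth:`alpha` or :meth:`tabulated`.
    """

    kind: str
    v_T: float
    v_R: float
    tau_ref: float
    kappa: float | None = None
    delta_v: float | None = None
    t0: float | None = None
    beta: float | None = None
    table: np.ndarray | None = field(default=None, repr=False)

    # -- constructors ------------------------------------------------------

    @classmethod
    def clamp(cls, tau_ref: float, v_T: float = 1.0, v_R: float = 0.0) -> "SpikeShape":
        if tau_ref <= 0:
            raise ShapeParameterError(f"tau_ref must be positive, got {tau_ref}")
        return cls(kind="clamp", v_T=v_T, v_R=v_R, tau_ref=tau_ref)

    @classmethod
    def alpha(
        cls,
        kappa: float,
        delta_v: float,
        tau_ref: float,
        v_T: float = 1.0,
        v_R: float = 0.0,
    ) -> "SpikeShape":
        t0, beta = solve_alpha_params(kappa, delta_v, tau_ref, v_T, v_R)
        return cls(
            kind="alpha", v_T=v_T, v_R=v_R, tau_ref=tau_ref,
            kappa=kappa, delta_v=delta_v, t0=t0, beta=beta,
        )

    @classmethod
    def tabulated(
        cls, t: np.ndarray, v: np.ndarray, dv: np.ndarray
    ) -> "SpikeShape":
        t = np.asarray(t, float)
        v = np.asarray(v, float)
        dv = np.asarray(dv, float)
        if not (t.shape == v.shape == dv.shape) or t.ndim != 1 or t.size < 2:
            raise ShapeParameterError("table needs matching 1-d t, v, dv columns")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ShapeParameterError("table times must start at 0 and increase")
        table = np.column_stack([t, v, dv])
        return cls(
            kind="tabulated", v_T=float(v[0]), v_R=float(v[-1]),
            tau_ref=float(t[-1]), table=table,
        )

    # -- evaluation --------------------------------------------------------

    def _check_domain(self, t: np.ndarray) -> None:
        if np.any(t < 0) or np.any(t > self.tau_ref * (1 + 1e-12)):
            raise ValueError(
                f"time outside the refractory interval [0, {self.tau_ref}]"
            )

    def value(self, t):
        """Evaluate ``v_spike(t)`` for ``t`` in ``[0, tau_ref]``."""
        t_arr = np.asarray(t, float)
        self._check_domain(t_arr)
        if self.kind == "clamp":
            out = np.where(t_arr > 0, self.v_R, self.v_T)
        elif self.kind == "alpha":
            out = self.kappa * (t_arr + self.t0) * np.exp(-self.beta * t_arr) - self.delta_v
        else:
            out = np.interp(t_arr, self.table[:, 0], self.table[:, 1])
        return out if isinstance(t, np.ndarray) else float(out)

    __call__ = value

    def derivative(self, t):
        """Evaluate ``dv_spike/dt``.

        For the clamp shape the derivative at ``t = 0`` is a Dirac impulse of
        weight ``v_R - v_T``; requesting it pointwise returns the
        :class:`Impulse` record rather than a float.
        """
        if self.kind == "clamp":
            t_arr = np.asarray(t, float)
            self._check_domain(t_arr)
            if np.any(t_arr == 0.0):
                if t_arr.ndim == 0:
                    return Impulse(0.0, self.v_R - self.v_T)
                raise ValueError(
                    "clamp derivative at t=0 is an impulse; use .impulse"
                )
            out = np.zeros_like(t_arr)
        elif self.kind == "alpha":
            t_arr = np.asarray(t, float)
            self._check_domain(t_arr)
            out = self.kappa * (1.0 - self.beta * (t_arr + self.t0)) * np.exp(-self.beta * t_arr)
        else:
            t_arr = np.asarray(t, float)
            self._check_domain(t_arr)
            out = np.interp(t_arr, self.table[:, 0], self.table[:, 2])
        return out if isinstance(t, np.ndarray) else float(out)

    @property
    def impulse(self) -> Impulse | None:
        """Boundary impulse of the derivative, if any (clamp only)."""
        if self.kind == "clamp":
            return Impulse(0.0, self.v_R - self.v_T)
        return None

    def sample(self, dt: float) -> np.ndarray:
        """Voltage table on the simulation grid ``t = 0, dt, ..., tau_ref``."""
        n = int(round(self.tau_ref / dt))
        t = np.arange(n + 1) * dt
        t[-1] = self.tau_ref  # guard rounding past the right edge
        return np.asarray(self.value(t), float)

    # -- serialization -----------------------------------------------------

    def to_config(self) -> dict:
        cfg = {"kind": self.kind, "v_T": self.v_T, "v_R": self.v_R,
               "tau_ref": self.tau_ref}
        if self.kind == "alpha":
            cfg.update(kappa=self.kappa, delta_v=self.delta_v)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "SpikeShape":
        kind = cfg["kind"]
        if kind == "clamp":
            return cls.clamp(cfg["tau_ref"], cfg.get("v_T", 1.0), cfg.get("v_R", 0.0))
        if kind == "alpha":
            return cls.alpha(cfg["kappa"], cfg["delta_v"], cfg["tau_ref"],
                             cfg.get("v_T", 1.0), cfg.get("v_R", 0.0))
        raise ShapeParameterError(f"unknown shape kind {kind!r} in config")

    def write_table(self, path, dt: float | None = None) -> None:
        """Write the waveform as 3-column text (t, v, dv/dt) with a header."""
        if self.kind == "tabulated":
            tab = self.table
        else:
            dt = dt or self.tau_ref / 256
            t = np.arange(int(round(self.tau_ref / dt)) + 1) * dt
            t[-1] = self.tau_ref
            v = np.asarray(self.value(t), float)
            dv = np.gradient(v, t) if self.kind == "clamp" else np.asarray(
                self.derivative(t), float)
            tab = np.column_stack([t, v, dv])
        np.savetxt(path, tab, header="t v_spike dv_spike_dt")

    @classmethod
    def read_table(cls, path) -> "SpikeShape":
        tab = np.loadtxt(path)
        return cls.tabulated(tab[:, 0], tab[:, 1], tab[:, 2])


def snap_to_grid(tau_ref: float, dt: float) -> float:
    """Round ``tau_ref`` to an integer multiple of the step ``dt``.

    Spectral identities involving the boxcar transform are exact only when
    the refractory period sits on the simulation grid.  A deviation beyond
    1e-9 relative triggers a warning.
    """
    n = round(tau_ref / dt)
    snapped = n * dt
    if abs(snapped - tau_ref) > 1e-9 * max(tau_ref, dt):
        warnings.warn(
            f"tau_ref={tau_ref} is not a multiple of dt={dt}; "
            f"rounded to {snapped}", stacklevel=2,
        )
    return snapped


def boxcar_ft(tau_ref: float, omega):
    """Fourier transform of the refractory boxcar ``B_tau_ref``.

    ``B_tilde(omega) = (exp(i*omega*tau_ref) - 1) / (i*omega)`` with the
    limit ``tau_ref`` at ``omega = 0``.
    """
    if tau_ref <= 0:
        raise ValueError("tau_ref must be positive")
    w = np.asarray(omega, float)
    out = np.empty(w.shape, complex)
    nz = w != 0
    wn = w[nz]
    out[nz] = (np.exp(1j * wn * tau_ref) - 1.0) / (1j * wn)
    out[~nz] = tau_ref
    return out if isinstance(omega, np.ndarray) else complex(out)


@dataclass(frozen=True)
class RefractoryCurrentFT:
    """Fourier transform of the single-spike refractory input current.

    ``values[k]`` holds ``FI(omega_grid[k]) = int_0^tau_ref exp(i*omega*t) *
    [f(v_spike(t)) - dv_spike/dt(t)] dt`` including the full weight of any
    boundary impulse of the derivative.  ``sign_convention`` records the
    impulse orientation: ``"audited"`` means the clamp impulse enters as
    ``+(v_T - v_R)``, the choice under which the white-noise FRR is exact.
    """

    omega_grid: np.ndarray
    values: np.ndarray
    shape: SpikeShape
    sign_convention: str = "audited"

    def __post_init__(self):
        if self.omega_grid.shape != self.values.shape:
            raise ValueError("omega grid and values must align")


def _drift_callable(drift) -> Callable[[np.ndarray], np.ndarray]:
    """Accept a ModelSpec-like object, a float mu (leaky drift), or f(v)."""
    if callable(drift):
        return drift
    if hasattr(drift, "f"):
        return drift.f
    mu = float(drift)
    return lambda v: mu - v


def clamp_refractory_ft_lif(
    mu: float, v_T: float, v_R: float, tau_ref: float, omega
) -> np.ndarray:
    """Closed form of ``FI`` for the clamped shape and leaky drift.

    ``FI(omega) = (mu - v_R) * B_tilde(omega) + (v_T - v_R)``: a boxcar
    carrying the constant drift ``mu - v_R`` seen at the clamped voltage,
    plus the full weight of the reset impulse.  The ``omega -> 0`` limit is
    ``(mu - v_R)*tau_ref + (v_T - v_R)``.
    """
    return (mu - v_R) * np.asarray(boxcar_ft(tau_ref, np.asarray(omega, float))) \
        + (v_T - v_R)


def refractory_current_ft(
    shape: SpikeShape,
    drift,
    omega: np.ndarray,
    n_quad: int = 2049,
    sign_convention: str = "audited",
) -> RefractoryCurrentFT:
    """Fourier transform of the refractory current for an arbitrary shape.

    For the clamp shape with a leaky drift the closed form
    :func:`clamp_refractory_ft_lif` is used; otherwise the integral is done
    by composite Simpson quadrature on ``n_quad`` points (the integrand is
    smooth for alpha/tabulated shapes).  ``sign_convention="negated"``
    returns the overall-negated transform.
    """
    omega = np.asarray(omega, float)
    f = _drift_callable(drift)
    is_lif_like = not callable(drift) and (
        not hasattr(drift, "f") or getattr(drift, "is_lif", False)
    )
    if hasattr(drift, "is_lif") and drift.is_lif:
        is_lif_like = True

    if shape.kind == "clamp" and is_lif_like:
        mu = drift.mu if hasattr(drift, "mu") else float(drift)
        vals = clamp_refractory_ft_lif(mu, shape.v_T, shape.v_R, shape.tau_ref, omega)
    else:
        if n_quad % 2 == 0:
            n_quad += 1
        t = np.linspace(0.0, shape.tau_ref, n_quad)
        v = np.asarray(shape.value(t), float)
        if shape.kind == "clamp":
            dv = np.zeros_like(t)
        else:
            dv = np.asarray(shape.derivative(t), float)
        g = f(v) - dv
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("drift non-finite on the spike-shape range")
        vals = _simpson_ft(g, t, omega)
        imp = shape.impulse
        if imp is not None:
            # full impulse weight of -dv_spike/dt: -(v_R - v_T) = v_T - v_R
            vals = vals + (-imp.weight) * np.exp(1j * omega * imp.time)
    if sign_convention == "negated":
        vals = -vals
    elif sign_convention != "audited":
        raise ValueError(f"unknown sign_convention {sign_convention!r}")
    return RefractoryCurrentFT(omega_grid=omega, values=vals, shape=shape,
                               sign_convention=sign_convention)


def _simpson_ft(g: np.ndarray, t: np.ndarray, omega: np.ndarray,
                block: int = 512) -> np.ndarray:
    """``int g(t) exp(i w t) dt`` by Simpson's rule, blocked over omega."""
    from scipy.integrate import simpson

    out = np.empty(omega.shape, complex)
    flat = omega.ravel()
    res = out.ravel()
    for i in range(0, flat.size, block):
        w = flat[i : i + block]
        kern = np.exp(1j * np.outer(w, t))
        res[i : i + block] = simpson(kern * g[None, :], x=t, axis=1)
    return out
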