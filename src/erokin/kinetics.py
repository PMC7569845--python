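"""Dynamical core: the autocatalytic erosion ODE and its RK4 integrator.

The model tracks the soluble-product mass fraction ``mu_S`` of a bulk-eroding
PLGA microsphere.  Acidic hydrolysis products act autocatalytically through a
Michaelis-Menten-like rate law, switched on smoothly around the induction
time ``t_ind``::

    d(mu_S)/dt = B0 * (1 - mu_S) / (1 + psi * omega_P(t) - mu_S)
                 * (tanh(alpha * (t - t_ind)) + 1) / 2

with ``omega_P(t) = exp(-k_deg * t)`` the nondimensional polymer molecular
weight (first-order chain scission) and initial condition ``mu_S(0) = 0``.
The residual-polymer fraction is ``mu_P = 1 - mu_S`` and the nondimensional
degradation-front radius is ``R_f = mu_S**(1/3)``: the solubilised core of
radius ``R_f`` grows outward until the sphere is fully eroded.

``omega_P`` is closed-form, so the system is a single scalar ODE integrated
here with a fixed-step classical Runge-Kutta scheme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "omega_p",
    "smooth_switch",
    "rhs_mu_s",
    "front_radius",
    "integrate_rk4",
    "simulate_front",
    "simulate_mu_s",
    "DegradationCurve",
    "IntegrationError",
]

logger = logging.getLogger(__name__)

DEFAULT_DT = 0.05  # day; B0 ~ 0.03/day makes the system non-stiff at this step

# pre-clamp overshoot beyond [0, 1] worth warning about
_CLAMP_WARN = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


def omega_p(t, k_deg):
    """Nondimensional polymer molecular weight ``exp(-k_deg * t)``.

    Accepts scalars or arrays; ``t`` and ``k_deg`` must be non-negative.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if k_deg < 0:
        raise ValueError("k_deg must be >= 0")
    out = np.exp(-k_deg * t)
    return out.item() if out.ndim == 0 else out


def smooth_switch(t, t_ind, alpha):
    """Mollified Heaviside step ``(tanh(alpha*(t - t_ind)) + 1) / 2``.

    Rises from 0 to 1 around ``t_ind`` over a width ~``1/alpha``; equals 0.5
    at ``t = t_ind`` and tends to the sharp step as ``alpha -> inf``.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    t = np.asarray(t, dtype=float)
    out = 0.5 * (np.tanh(alpha * (t - t_ind)) + 1.0)
    return out.item() if out.ndim == 0 else out


def rhs_mu_s(t: float, mu_s: float, p: ModelParams) -> float:
    """Time derivative of the soluble mass fraction.

    Non-negative and bounded above by ``p.b0``; vanishes as ``mu_s -> 1``.
    """
    if not 0.0 <= mu_s <= 1.0:
        raise ValueError(f"mu_s must lie in [0, 1], got {mu_s}")
    return _rhs(t, mu_s, p.b0, p.psi, p.t_ind, p.k_deg, p.alpha, True)


def _rhs(t, mu_s, b0, psi, t_ind, k_deg, alpha, smooth):
    # scalar fast path used inside the RK4 loop
    one_minus = 1.0 - mu_s
    denom = psi * math.exp(-k_deg * t) + one_minus
    if smooth:
        sw = 0.5 * (math.tanh(alpha * (t - t_ind)) + 1.0)
    else:
        # sharp Heaviside variant (H(0) = 0.5, matching the tanh mollifier)
        sw = 0.0 if t < t_ind else (0.5 if t == t_ind else 1.0)
    if denom <= 0.0:  # only reachable through float round-off at mu_s ~ 1
        return 0.0
    return b0 * one_minus / denom * sw


def front_radius(mu_s):
    """Nondimensional degradation-front radius ``mu_s**(1/3)``.

    Inverse of the shell-volume balance ``mu_P = 1 - R_f**3``.
    """
    mu_s = np.asarray(mu_s, dtype=float)
    if np.any((mu_s < 0) | (mu_s > 1)):
        raise ValueError("mu_s must lie in [0, 1]")
    out = np.cbrt(mu_s)
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class DegradationCurve:
    """A simulated trajectory on a strictly increasing time grid from t = 0.

    Attributes are parallel arrays: ``t`` (day), soluble fraction ``mu_s``,
    residual fraction ``mu_p = 1 - mu_s``, nondimensional molecular weight
    ``omega_p`` and front radius ``r_f = mu_s**(1/3)``.
    """

    t: np.ndarray
    mu_s: np.ndarray
    mu_p: np.ndarray
    omega_p: np.ndarray
    r_f: np.ndarray

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_day": self.t,
                "mu_S": self.mu_s,
                "mu_P": self.mu_p,
                "omega_P": self.omega_p,
                "R_f": self.r_f,
            }
        )

    def interp_r_f(self, times) -> np.ndarray:
        """Front radius at arbitrary times within the grid (linear interp)."""
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < self.t[0] or times.max() > self.t[-1]):
            raise ValueError("requested times outside the integrated range")
        return np.interp(times, self.t, self.r_f)

    def interp_mu_s(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if times.size and (times.min() < self.t[0] or times.max() > self.t[-1]):
            raise ValueError("requested times outside the integrated range")
        return np.interp(times, self.t, self.mu_s)


def _time_grid(t_end: float, dt: float) -> np.ndarray:
    n = int(math.ceil(t_end / dt - 1e-12))
    grid = dt * np.arange(n + 1, dtype=float)
    grid[-1] = t_end  # final step shortened so the grid ends exactly at t_end
    return grid


def integrate_rk4(
    p: ModelParams,
    t_end: float,
    dt: float = DEFAULT_DT,
    *,
    switch: str = "smooth",
) -> DegradationCurve:
    """Integrate the erosion ODE with the classical fixed-step RK4 scheme.

    Parameters
    ----------
    p : ModelParams
        Kinetic constants.
    t_end, dt : float
        Integration horizon and step, days; ``0 < dt <= t_end``.  The final
        step is shortened so the grid ends exactly at ``t_end``.
    switch : {"smooth", "heaviside"}
        Induction switch variant.  ``"smooth"`` is the mollified tanh model;
        ``"heaviside"`` uses the sharp step (useful to check the
        ``alpha -> inf`` limit).

    Returns
    -------
    DegradationCurve

    Notes
    -----
    After each step ``mu_s`` is clamped to [0, 1]; round-off can push the
    state marginally past the ``mu_s = 1`` asymptote.  An excursion beyond
    1e-9 is logged as a warning.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if not 0 < dt <= t_end:
        raise ValueError("dt must satisfy 0 < dt <= t_end")
    if switch not in ("smooth", "heaviside"):
        raise ValueError(f"unknown switch variant {switch!r}")
    smooth = switch == "smooth"

    grid = _time_grid(t_end, dt)
    mu = np.empty_like(grid)
    mu[0] = 0.0  # no soluble products before immersion

    b0, psi, t_ind, k_deg, alpha = p.b0, p.psi, p.t_ind, p.k_deg, p.alpha
    y = 0.0
    max_excursion = 0.0
    for i in range(grid.size - 1):
        t0 = grid[i]
        h = grid[i + 1] - t0
        k1 = _rhs(t0, y, b0, psi, t_ind, k_deg, alpha, smooth)
        y2 = min(y + 0.5 * h * k1, 1.0)
        k2 = _rhs(t0 + 0.5 * h, y2, b0, psi, t_ind, k_deg, alpha, smooth)
        y3 = min(y + 0.5 * h * k2, 1.0)
        k3 = _rhs(t0 + 0.5 * h, y3, b0, psi, t_ind, k_deg, alpha, smooth)
        y4 = min(y + h * k3, 1.0)
        k4 = _rhs(t0 + h, y4, b0, psi, t_ind, k_deg, alpha, smooth)
        y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not math.isfinite(y):
            raise IntegrationError(
                f"non-finite mu_S at step {i + 1} (t = {grid[i + 1]:g} day)"
            )
        if y > 1.0:
            max_excursion = max(max_excursion, y - 1.0)
            y = 1.0
        elif y < 0.0:
            max_excursion = max(max_excursion, -y)
            y = 0.0
        mu[i + 1] = y
    if max_excursion > _CLAMP_WARN:
        logger.warning(
            "mu_S clamped to [0, 1]; largest excursion %.3e", max_excursion
        )

    return DegradationCurve(
        t=grid,
        mu_s=mu,
        mu_p=1.0 - mu,
        omega_p=np.exp(-k_deg * grid),
        r_f=np.cbrt(mu),
    )


def simulate_front(
    p: ModelParams, times, dt: float = DEFAULT_DT, *, switch: str = "smooth"
) -> np.ndarray:
    """Front radius ``R_f`` at the requested times (integrates, then interpolates)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    t_end = float(times.max()) if times.size else 0.0
    if t_end == 0.0:
        return np.zeros_like(times)
    curve = integrate_rk4(p, t_end, dt, switch=switch)
    return curve.interp_r_f(times)


def simulate_mu_s(
    p: ModelParams, times, dt: float = DEFAULT_DT, *, switch: str = "smooth"
) -> np.ndarray:
    """Soluble mass fraction ``mu_S`` at the requested times."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    t_end = float(times.max()) if times.size else 0.0
    if t_end == 0.0:
        return np.zeros_like(times)
    curve = integrate_rk4(p, t_end, dt, switch=switch)
    return curve.interp_mu_s(times)
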