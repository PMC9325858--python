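"""International Equation of State of Seawater 1980 (EOS-80).

Implements the UNESCO 1983 polynomials (Fofonoff & Millard algorithms) for
in-situ density, the adiabatic lapse rate, potential temperature and the
potential density anomaly sigma-theta, together with a monotone inversion of
sigma-theta for practical salinity.  This is the density formulation used for
pressure-aware salinity reconstructions at coral-mound water depths; TEOS-10
is deliberately not used (see :func:`register_crosscheck` for the optional
comparison hook).

Units follow the oceanographic convention: salinity on the practical scale
(numerically g/kg here), temperature in deg C (IPTS-68 vs ITS-90 differences,
< 0.002 deg C, are ignored), pressure in decibars above atmospheric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HydroState",
    "EnvelopeError",
    "DensityUnattainableError",
    "density_eos80",
    "potential_temperature",
    "sigma_theta",
    "salinity_from_sigma_theta",
    "adiabatic_lapse_rate",
    "pressure_from_depth",
    "register_crosscheck",
    "crosscheck",
]

# Validity envelope of the EOS-80 fit.
S_MIN, S_MAX = 0.0, 42.0
T_MIN, T_MAX = -2.0, 40.0
P_MIN, P_MAX = 0.0, 12000.0

#: dbar per metre for shallow-shelf depths; the exact Saunders formula differs
#: negligibly above a few hundred metres.
DBAR_PER_METER = 1.0053


class EnvelopeError(ValueError):
    """Input outside the EOS-80 validity envelope; names the offending field."""


class DensityUnattainableError(ValueError):
    """No salinity in [0, 42] attains the requested sigma-theta at this T, p."""


def _check_envelope(salinity, temperature, pressure) -> None:
    s = np.asarray(salinity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(pressure, dtype=float)
    if np.any(~np.isfinite(s)) or np.any((s < S_MIN) | (s > S_MAX)):
        raise EnvelopeError(
            f"salinity outside EOS-80 envelope [{S_MIN}, {S_MAX}] g/kg"
        )
    if np.any(~np.isfinite(t)) or np.any((t < T_MIN) | (t > T_MAX)):
        raise EnvelopeError(
            f"temperature outside EOS-80 envelope [{T_MIN}, {T_MAX}] degC"
        )
    if np.any(~np.isfinite(p)) or np.any((p < P_MIN) | (p > P_MAX)):
        raise EnvelopeError(
            f"pressure outside EOS-80 envelope [{P_MIN}, {P_MAX}] dbar"
        )


@dataclass(frozen=True)
class HydroState:
    """A hydrographic state (S, T, p) with its potential density anomaly."""

    salinity: float
    temperature: float
    pressure: float
    sigma_theta: float

    @classmethod
    def from_stp(cls, salinity: float, temperature: float, pressure: float) -> "HydroState":
        return cls(
            salinity=float(salinity),
            temperature=float(temperature),
            pressure=float(pressure),
            sigma_theta=float(sigma_theta(salinity, temperature, pressure)),
        )


def pressure_from_depth(depth_m, factor: float = DBAR_PER_METER):
    """Approximate sea pressure (dbar) from depth (m); linear shallow-shelf rule."""
    return np.asarray(depth_m, dtype=float) * factor


def _density_atmospheric(s, t):
    # Density of standard mean ocean water (Bigg 1967 fit), then the
    # one-atmosphere seawater terms of the 1980 equation of state.
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s * np.sqrt(s) + c * s**2


def _secant_bulk_modulus(s, t, p_bar):
    sr = np.sqrt(s)
    kw = (
        19652.21
        + 148.4206 * t
        - 2.327105 * t**2
        + 1.360477e-2 * t**3
        - 5.155288e-5 * t**4
    )
    k0 = (
        kw
        + s * (54.6746 - 0.603459 * t + 1.09987e-2 * t**2 - 6.1670e-5 * t**3)
        + s * sr * (7.944e-2 + 1.6483e-2 * t - 5.3009e-4 * t**2)
    )
    aw = 3.239908 + 1.43713e-3 * t + 1.16092e-4 * t**2 - 5.77905e-7 * t**3
    a = aw + s * (2.2838e-3 - 1.0981e-5 * t - 1.6078e-6 * t**2) + 1.91075e-4 * s * sr
    bw = 8.50935e-5 - 6.12293e-6 * t + 5.2787e-8 * t**2
    b = bw + s * (-9.9348e-7 + 2.0816e-8 * t + 9.1697e-10 * t**2)
    return k0 + a * p_bar + b * p_bar**2


def _density_unchecked(salinity, temperature, pressure):
    s = np.asarray(salinity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    p_bar = np.asarray(pressure, dtype=float) / 10.0  # dbar -> bar
    rho0 = _density_atmospheric(s, t)
    k = _secant_bulk_modulus(s, t, p_bar)
    rho = rho0 / (1.0 - p_bar / k)
    return float(rho) if rho.ndim == 0 else rho


def density_eos80(salinity, temperature, pressure):
    """In-situ density rho(S, T, p) in kg/m3 per the 1980 equation of state.

    ``pressure`` is sea pressure in dbar; the high-pressure correction uses the
    secant bulk modulus. Scalar inputs return a float; array inputs broadcast.
    """
    _check_envelope(salinity, temperature, pressure)
    return _density_unchecked(salinity, temperature, pressure)


def adiabatic_lapse_rate(salinity, temperature, pressure):
    """Adiabatic temperature gradient (deg C / dbar), Fofonoff & Millard fit."""
    s = np.asarray(salinity, dtype=float) - 35.0
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(pressure, dtype=float)
    atg = (
        3.5803e-5
        + 8.5258e-6 * t
        - 6.836e-8 * t**2
        + 6.6228e-10 * t**3
        + (1.8932e-6 - 4.2393e-8 * t) * s
        + (1.8741e-8 - 6.7795e-10 * t + 8.733e-12 * t**2 - 5.4481e-14 * t**3) * p
        + (-1.1351e-10 + 2.7759e-12 * t) * s * p
        + (-4.6206e-13 + 1.8676e-14 * t - 2.1687e-16 * t**2) * p**2
    )
    return float(atg) if atg.ndim == 0 else atg


def potential_temperature(salinity, temperature, pressure, reference_pressure=0.0):
    """Potential temperature theta (deg C) at ``reference_pressure``.

    Integrates the adiabatic lapse rate from ``pressure`` to the reference
    pressure with the classic single 4th-order Runge-Kutta step (Fofonoff
    1977); accurate to well below 1 mK for displacements of a few hundred dbar.
    """
    _check_envelope(salinity, temperature, pressure)
    s = np.asarray(salinity, dtype=float)
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(pressure, dtype=float)
    pr = np.asarray(reference_pressure, dtype=float)

    h = pr - p
    xk = h * adiabatic_lapse_rate(s, t, p)
    t = t + 0.5 * xk
    q = xk
    xk = h * adiabatic_lapse_rate(s, t, p + 0.5 * h)
    t = t + 0.29289322 * (xk - q)
    q = 0.58578644 * xk + 0.121320344 * q
    xk = h * adiabatic_lapse_rate(s, t, p + 0.5 * h)
    t = t + 1.707106781 * (xk - q)
    q = 3.414213562 * xk - 4.121320344 * q
    xk = h * adiabatic_lapse_rate(s, t, p + h)
    theta = t + (xk - 2.0 * q) / 6.0
    return float(theta) if theta.ndim == 0 else theta


def sigma_theta(salinity, temperature, pressure):
    """Potential density anomaly sigma-theta (kg/m3), reference pressure 0 dbar.

    The envelope check applies to the in-situ inputs; the adiabatically
    displaced temperature may validly fall slightly outside it and is not
    re-validated.
    """
    theta = potential_temperature(salinity, temperature, pressure, 0.0)
    return _density_unchecked(salinity, theta, 0.0) - 1000.0


def salinity_from_sigma_theta(sigma_theta_target: float, temperature: float,
                              pressure: float, tol: float = 1e-6) -> float:
    """Invert sigma-theta for practical salinity at fixed (T, p).

    Sigma-theta increases strictly with salinity at fixed temperature and
    pressure, so the root on S in [0, 42] is unique when it exists.

    Raises
    ------
    DensityUnattainableError
        If the target density anomaly lies outside what any salinity in
        [0, 42] can produce at this temperature and pressure.
    """
    target = float(sigma_theta_target)
    lo = sigma_theta(S_MIN, temperature, pressure)
    hi = sigma_theta(S_MAX, temperature, pressure)
    if not (lo <= target <= hi):
        raise DensityUnattainableError(
            f"density anomaly {target:.4f} kg/m3 unattainable at this temperature "
            f"(attainable range [{lo:.4f}, {hi:.4f}] for S in [0, 42])"
        )
    return brentq(
        lambda s: sigma_theta(s, temperature, pressure) - target,
        S_MIN, S_MAX, xtol=tol,
    )


# ---------------------------------------------------------------------------
# Optional cross-check hook against an alternative equation of state
# (e.g. a TEOS-10 toolbox).  Expected sigma-theta offsets at shelf conditions
# are below 0.01 kg/m3; the hook lets a user quantify them without making the
# alternative formulation a dependency.

_crosscheck_fn: Optional[Callable[[float, float, float], float]] = None


def register_crosscheck(fn: Optional[Callable[[float, float, float], float]]) -> None:
    """Register ``fn(S, T, p) -> sigma_theta`` from an alternative formulation."""
    global _crosscheck_fn
    _crosscheck_fn = fn


def crosscheck(salinity: float, temperature: float, pressure: float) -> Optional[float]:
    """Offset (alternative minus EOS-80) in sigma-theta, or None if no hook set."""
    if _crosscheck_fn is None:
        return None
    return _crosscheck_fn(salinity, temperature, pressure) - sigma_theta(
        salinity, temperature, pressure
    )
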