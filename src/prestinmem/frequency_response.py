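"""Prestin electrical filter and the isometric active force response.

Under isometric conditions the total strain is zero, so the passive strain
cancels the prestin-driven active strain (which is proportional, with the
coupling products alpha_i*C_sp, to the transferred charge).  The resulting
axial resultant amplitude is

    |F|(omega)  proportional to  |a1 C*_11(omega) + a2 C*_12(omega)| * q0(omega)

with ``a_i = alpha_i C_sp`` and ``q0 = C_sp V0 / sqrt(1 + (omega tau_e)^2)``
the first-order-filtered charge amplitude.  Normalizing by the analytic
omega -> 0 limit gives the dimensionless amplitude; the phase is the sum of
the (positive) viscoelastic phase of the numerator and the (negative)
prestin charge-transfer phase ``-atan(omega tau_e)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kernels import complex_modulus
from .parameters import OHCMembraneParams

__all__ = [
    "ForceResponse",
    "prestin_filter_ode",
    "prestin_filter_amplitude",
    "prestin_phase",
    "harmonic_charge_amplitude",
    "force_numerator_denominator",
    "isometric_force",
]


@dataclass(frozen=True)
class ForceResponse:
    """Normalized isometric force amplitude and phase over a frequency grid."""

    omega: np.ndarray
    amplitude_norm: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))
        object.__setattr__(self, "amplitude_norm", np.asarray(self.amplitude_norm, dtype=float))
        object.__setattr__(self, "phase", np.asarray(self.phase, dtype=float))


# ---------------------------------------------------------------------------
# Prestin charge-transfer filter
# ---------------------------------------------------------------------------

def prestin_filter_ode(
    V_of_t: Callable[[np.ndarray], np.ndarray],
    tau_e: float,
    t_grid: np.ndarray,
    f: Callable[[np.ndarray], np.ndarray] | None = None,
    y0: float = 0.0,
) -> np.ndarray:
    """Solve the charge-transfer relaxation ODE  tau_e dP' + P = f(V(t)).

    The probability of charge transfer relaxes toward the voltage function
    ``f(V)`` (identity by default) with time constant ``tau_e``.  The linear
    ODE is integrated exactly on each sub-interval with an exponential
    integrator (trapezoidal treatment of the forcing), which is accurate to
    O(h^2 f'') — use a fine grid for oscillatory forcing.

    Returns the trajectory of deltaP* on ``t_grid``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D, increasing, with at least two points")
    if tau_e <= 0:
        raise ValueError("tau_e must be positive")
    forcing = np.asarray(V_of_t(t), dtype=float)
    if f is not None:
        forcing = np.asarray(f(forcing), dtype=float)
    y = np.empty_like(t)
    y[0] = y0
    h = np.diff(t)
    e = np.exp(-h / tau_e)
    # exact solution for piecewise-linear forcing on each sub-interval
    g0 = forcing[:-1]
    g1 = forcing[1:]
    slope = (g1 - g0) / h
    for k in range(t.size - 1):
        # y(t+h) = g1 - slope*tau + (y - g0 + slope*tau) * exp(-h/tau)
        y[k + 1] = g1[k] - slope[k] * tau_e + (y[k] - g0[k] + slope[k] * tau_e) * e[k]
    return y


def prestin_filter_amplitude(omega, tau_e: float) -> np.ndarray:
    """Steady-state amplitude factor 1/sqrt(1 + (omega tau_e)^2)."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    return 1.0 / np.sqrt(1.0 + (omega * tau_e) ** 2)


def prestin_phase(omega, tau_e: float) -> np.ndarray:
    """Prestin charge-transfer phase shift, -atan(omega tau_e), rad.

    Zero at omega = 0, monotonically decreasing toward -pi/2.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    return -np.arctan(omega * tau_e)


def harmonic_charge_amplitude(params: OHCMembraneParams, V0: float, omega) -> np.ndarray:
    """Amplitude q0 of the harmonically transferred charge, C/m^2.

    ``q0 = C_sp V0 / sqrt(1 + (omega tau_e)^2)``; equals ``C_sp V0`` in the
    capacitive (omega -> 0) limit.
    """
    if V0 < 0:
        raise ValueError("V0 must be non-negative")
    return params.C_sp * V0 * prestin_filter_amplitude(omega, params.tau_e)


# ---------------------------------------------------------------------------
# Isometric force
# ---------------------------------------------------------------------------

def _effective_params(
    params: OHCMembraneParams, model: str, eta_kv: float | None
) -> OHCMembraneParams:
    if model == "power_law":
        return params
    if model == "kelvin_voigt":
        if eta_kv is None:
            raise ValueError("kelvin_voigt mode requires eta_kv (N s / m)")
        return params.replace(nu=1.0, eta=eta_kv)
    raise ValueError(f"unknown model {model!r}")


def _numerator_complex(params: OHCMembraneParams, omega: np.ndarray) -> np.ndarray:
    """a1 C*_11 + a2 C*_12 on the grid (complex, N/(m V))."""
    Cstar = complex_modulus(params, omega)
    a1, a2 = params.alpha1_Csp, params.alpha2_Csp
    return a1 * Cstar[..., 0, 0] + a2 * Cstar[..., 0, 1]


def _numerator_complex_isometric_system(
    params: OHCMembraneParams, omega: np.ndarray
) -> np.ndarray:
    """Independent route: solve the isometric system explicitly.

    Sets the total strain to zero, so the passive strain is minus the active
    strain (per unit transferred charge: -(a1, a2)), applies the full complex
    modulus matrix to obtain both resultants, and returns minus the axial
    resultant.  Must agree with the closed-form numerator.
    """
    Cstar = complex_modulus(params, omega)
    eps_passive = -np.array([params.alpha1_Csp, params.alpha2_Csp])
    N = Cstar @ eps_passive  # (..., 2)
    return -N[..., 0]


def force_numerator_denominator(
    params: OHCMembraneParams,
    omega,
    model: str = "power_law",
    eta_kv: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitudes of the viscoelastic numerator and prestin denominator.

    Returns ``(|a1 C*_11 + a2 C*_12| / |a1 C11 + a2 C12|,
    sqrt(1 + (omega tau_e)^2))``; the normalized force amplitude is their
    ratio.  Both factors increase monotonically with frequency for eta > 0.
    """
    omega = np.asarray(omega, dtype=float)
    p = _effective_params(params, model, eta_kv)
    num0 = p.alpha1_Csp * p.C11 + p.alpha2_Csp * p.C12
    if num0 == 0:
        raise ZeroDivisionError("zero elastic numerator: a1*C11 + a2*C12 = 0")
    num = np.abs(_numerator_complex(p, omega)) / abs(num0)
    den = np.sqrt(1.0 + (omega * p.tau_e) ** 2)
    return num, den


def isometric_force(
    params: OHCMembraneParams,
    omega_grid,
    model: str = "power_law",
    eta_kv: float | None = None,
) -> ForceResponse:
    """Normalized isometric active force amplitude and phase.

    Parameters
    ----------
    params : OHCMembraneParams
    omega_grid : array of float
        Angular frequencies, rad/s, positive and increasing.
    model : {"power_law", "kelvin_voigt"}
        ``kelvin_voigt`` substitutes nu = 1 with the caller-supplied
        viscosity ``eta_kv`` (N s/m), leaving all other parameters fixed.

    Notes
    -----
    The amplitude is normalized by the analytic omega -> 0 limit, so
    ``amplitude_norm -> 1`` and ``phase -> 0`` at low frequency.  The phase
    decomposes as (positive) viscoelastic numerator phase plus (negative)
    prestin phase.
    """
    omega = np.asarray(omega_grid, dtype=float)
    if omega.ndim != 1 or omega.size == 0:
        raise ValueError("omega_grid must be a non-empty 1-D array")
    if np.any(omega <= 0) or np.any(np.diff(omega) <= 0):
        raise ValueError("omega_grid must be positive and strictly increasing")
    p = _effective_params(params, model, eta_kv)
    num0 = p.alpha1_Csp * p.C11 + p.alpha2_Csp * p.C12
    if num0 == 0:
        raise ZeroDivisionError("zero elastic numerator: a1*C11 + a2*C12 = 0")
    # complex normalized response: numerator ratio times filtered charge phasor
    num_ratio = _numerator_complex(p, omega) / num0
    filt = prestin_filter_amplitude(omega, p.tau_e) * np.exp(
        1j * prestin_phase(omega, p.tau_e)
    )
    response = num_ratio * filt
    return ForceResponse(
        omega=omega,
        amplitude_norm=np.abs(response),
        phase=np.angle(response),
    )
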