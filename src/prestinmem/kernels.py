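"""Viscoelastic relaxation/creep kernels and the prestin electrical kernel.

The mechanical law is a springpot (power-law) element in parallel with the
elastic moduli: each relaxation entry is ``C + eta * t**(-nu) / Gamma(1-nu)``,
with Fourier-domain counterpart ``C + eta * (i omega)**nu`` (principal
branch, phase nu*pi/2).  Creep kernels are obtained from the matrix
reciprocity in the Laplace domain and inverted numerically (fixed Talbot as
the primary algorithm, Gaver-Stehfest as a cross-check).

The electrical (prestin charge-transfer) kernel is the rate form of a
series-RC step response with specific capacitance ``C_sp`` and RC time
``tau_e``.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.special import gamma as _gamma

from .parameters import OHCMembraneParams, SphereMembraneParams

__all__ = [
    "relaxation_kernel_ohc",
    "relaxation_kernel_sphere",
    "relaxation_laplace_matrix",
    "creep_kernel_laplace",
    "creep_kernel_time",
    "complex_modulus",
    "complex_modulus_sphere",
    "electrical_kernel",
    "electrical_step_response",
    "invert_laplace_talbot",
    "invert_laplace_stehfest",
    "LaplaceInversionError",
]


class LaplaceInversionError(RuntimeError):
    """Raised when a numerical Laplace inversion fails to converge."""


def _check_time(t: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be strictly positive (power-law kernel is singular at t = 0)")
    return t


def _springpot_relaxation(eta: float, nu: float, t: np.ndarray) -> np.ndarray:
    """Viscous part of the relaxation kernel: eta * t^(-nu) / Gamma(1-nu)."""
    if eta == 0.0:
        return np.zeros_like(t)
    if nu == 1.0:
        # Kelvin-Voigt limit: the springpot degenerates to a dashpot whose
        # relaxation contribution is impulsive; it has no regular t > 0 part.
        return np.zeros_like(t)
    return eta * t ** (-nu) / _gamma(1.0 - nu)


def relaxation_kernel_ohc(params: OHCMembraneParams, t) -> np.ndarray:
    """Relaxation kernel matrix E_ij(t) of the orthotropic OHC wall, N/m.

    Parameters
    ----------
    params : OHCMembraneParams
    t : float or array of float
        Times, s, strictly positive.

    Returns
    -------
    ndarray
        Shape ``(2, 2)`` for scalar ``t``, else ``t.shape + (2, 2)``.
    """
    t = _check_time(t)
    visc = _springpot_relaxation(params.eta, params.nu, t)
    C = params.elastic_matrix
    out = C + visc[..., None, None]
    return out


def relaxation_kernel_sphere(params: SphereMembraneParams, t) -> np.ndarray:
    """Relaxation kernel E(t) = K + eta t^(-nu)/Gamma(1-nu) of the sphere."""
    t = _check_time(t)
    return params.K + _springpot_relaxation(params.eta, params.nu, t)


# ---------------------------------------------------------------------------
# Laplace domain
# ---------------------------------------------------------------------------

def _springpot_s(eta: float, nu: float, s: complex) -> complex:
    return eta * s**nu


def relaxation_laplace_matrix(params: OHCMembraneParams, s: complex) -> np.ndarray:
    """Laplace transform of the relaxation kernel matrix, Ehat(s).

    ``Ehat(s) = (C + eta s^nu * ones(2,2)) / s``; the springpot term enters
    every entry, matching the time-domain kernel.
    """
    g = _springpot_s(params.eta, params.nu, s)
    return (params.elastic_matrix + g * np.ones((2, 2))) / s


def creep_kernel_laplace(params: OHCMembraneParams, s: complex) -> np.ndarray:
    """Laplace transform Jhat(s) of the 2x2 creep kernel matrix.

    Built from the explicit entries of the inverted relaxation matrix:
    with ``g = eta s^nu`` and determinant
    ``D = (C11+g)(C22+g) - (C12+g)^2``,

    ``s*Jhat = [[C22+g, -(C12+g)], [-(C12+g), C11+g]] / D``

    so that ``(s Jhat)(s Ehat) = I`` (viscoelastic reciprocity).

    Raises
    ------
    LaplaceInversionError
        If the relaxation matrix is numerically singular at ``s``.
    """
    if np.real(s) <= 0 and np.imag(s) == 0:
        raise ValueError("creep_kernel_laplace requires Re(s) > 0 (or complex s off the cut)")
    g = _springpot_s(params.eta, params.nu, s)
    a = params.C11 + g
    b = params.C12 + g
    c = params.C22 + g
    det = a * c - b * b
    if det == 0 or not np.isfinite(abs(det)):
        raise LaplaceInversionError(
            f"singular relaxation matrix at s = {s!r} (det = {det!r})"
        )
    inv = np.array([[c, -b], [-b, a]]) / det
    return inv / s


# -- numerical inversion ----------------------------------------------------

def invert_laplace_talbot(fhat: Callable[[complex], complex], t: float, m: int = 32) -> float:
    """Fixed-Talbot inversion of a scalar Laplace transform at time t > 0."""
    if t <= 0:
        raise ValueError("t must be positive")
    r = 2.0 * m / (5.0 * t)
    # theta = 0 term
    total = 0.5 * math.exp(r * t) * np.real(fhat(complex(r, 0.0)))
    for k in range(1, m):
        theta = k * math.pi / m
        cot = 1.0 / math.tan(theta)
        s = r * theta * complex(cot, 1.0)
        sigma = theta + (theta * cot - 1.0) * cot
        total += np.real(np.exp(t * s) * fhat(s) * complex(1.0, sigma))
    val = total * r / m
    if not np.isfinite(val):
        raise LaplaceInversionError(f"fixed-Talbot inversion diverged at t = {t}")
    return float(val)


def _stehfest_coeffs(n: int) -> np.ndarray:
    if n % 2:
        raise ValueError("Stehfest order must be even")
    V = np.zeros(n)
    half = n // 2
    for k in range(1, n + 1):
        acc = 0.0
        for j in range((k + 1) // 2, min(k, half) + 1):
            num = j**half * math.factorial(2 * j)
            den = (
                math.factorial(half - j)
                * math.factorial(j)
                * math.factorial(j - 1)
                * math.factorial(k - j)
                * math.factorial(2 * j - k)
            )
            acc += num / den
        V[k - 1] = (-1) ** (k + half) * acc
    return V


def invert_laplace_stehfest(fhat: Callable[[float], float], t: float, n: int = 14) -> float:
    """Gaver-Stehfest inversion (real s samples only); cross-check algorithm."""
    if t <= 0:
        raise ValueError("t must be positive")
    V = _stehfest_coeffs(n)
    ln2_t = math.log(2.0) / t
    total = 0.0
    for k in range(1, n + 1):
        total += V[k - 1] * np.real(fhat(k * ln2_t))
    val = total * ln2_t
    if not np.isfinite(val):
        raise LaplaceInversionError(f"Gaver-Stehfest inversion diverged at t = {t}")
    return float(val)


def creep_kernel_time(
    params: OHCMembraneParams,
    t,
    method: str = "talbot",
) -> np.ndarray:
    """Time-domain creep kernel matrix J(t), m/N, by numerical inversion.

    ``method`` selects the inversion algorithm: ``"talbot"`` (fixed Talbot,
    primary) or ``"stehfest"`` (Gaver-Stehfest, cross-check).  In the purely
    elastic limit (eta = 0) the inverse elastic matrix is returned exactly.
    """
    t = _check_time(t)
    scalar = t.ndim == 0
    tt = np.atleast_1d(t)
    if params.eta == 0.0:
        Jel = np.linalg.inv(params.elastic_matrix)
        out = np.broadcast_to(Jel, tt.shape + (2, 2)).copy()
        return out[0] if scalar else out

    invert = {"talbot": invert_laplace_talbot, "stehfest": invert_laplace_stehfest}
    if method not in invert:
        raise ValueError(f"unknown inversion method {method!r}")

    out = np.empty(tt.shape + (2, 2))
    for idx in ((0, 0), (0, 1), (1, 1)):
        i, j = idx

        def fhat(s, i=i, j=j):
            return creep_kernel_laplace(params, s)[i, j]

        for k, tk in enumerate(tt):
            out[k, i, j] = invert[method](fhat, float(tk))
    out[:, 1, 0] = out[:, 0, 1]
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

def _springpot_omega(eta: float, nu: float, omega: np.ndarray) -> np.ndarray:
    """eta * (i omega)^nu on the principal branch (phase nu*pi/2)."""
    phase = complex(math.cos(nu * math.pi / 2.0), math.sin(nu * math.pi / 2.0))
    return eta * omega**nu * phase


def complex_modulus(params: OHCMembraneParams, omega) -> np.ndarray:
    """Complex modulus matrix C*_ij(omega) = C_ij + eta (i omega)^nu, N/m.

    At ``omega = 0`` the entries equal the elastic moduli exactly; for
    ``nu = 1`` the entries reduce to the Kelvin-Voigt form ``C_ij + i omega
    eta``.

    Returns shape ``(2, 2)`` for scalar omega, else ``omega.shape + (2, 2)``.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    visc = _springpot_omega(params.eta, params.nu, omega)
    return params.elastic_matrix + visc[..., None, None] * np.ones((2, 2))


def complex_modulus_sphere(params: SphereMembraneParams, omega) -> np.ndarray:
    """Scalar complex modulus K*(omega) = K + eta (i omega)^nu, N/m."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    return params.K + _springpot_omega(params.eta, params.nu, omega)


# ---------------------------------------------------------------------------
# Electrical (prestin) kernel
# ---------------------------------------------------------------------------

def electrical_kernel(tau_e: float, C_sp: float, t) -> np.ndarray:
    """Prestin charge-transfer kernel (rate form), F/(m^2 s).

    ``k(t) = (C_sp / tau_e) exp(-t / tau_e)`` for t > 0.  Convolved with a
    voltage history V(tau), it yields the charge per unit area; for a unit
    voltage step the charge builds as ``C_sp (1 - exp(-t/tau_e))``.
    """
    t = _check_time(t)
    if tau_e <= 0:
        raise ValueError("tau_e must be positive")
    if C_sp <= 0:
        raise ValueError("C_sp must be positive")
    return (C_sp / tau_e) * np.exp(-t / tau_e)


def electrical_step_response(tau_e: float, C_sp: float, t, V: float = 1.0) -> np.ndarray:
    """Charge per unit area after a voltage step of height V at t = 0."""
    t = _check_time(t)
    return C_sp * V * (1.0 - np.exp(-t / tau_e))
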