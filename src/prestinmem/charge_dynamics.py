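"""Time-domain electric charge generated by mechanical loading.

All loadings are applied at t = 0 under voltage clamp (the membrane
potential is held fixed, so voltage terms drop from the constitutive
relations).  The charge per unit area is the hereditary convolution of the
electromechanical kernels (coupling products ``a_i = alpha_i C_sp`` times
the RC charge-transfer kernel) with the membrane resultant history:

    q(t) = sum_i a_i * (1/tau_e) * int_0^t exp(-(t-s)/tau_e) N_i(s) ds

For internal pressure dP on a cylinder of radius r_c the resultants are
``N1 = dP r_c / 2`` (axial) and ``N2 = dP r_c`` (circumferential); for a
sphere ``N = dP r_c / 2``.  For a constant axial strain rate on a
volume-conserving cylinder the circumferential rate is ``-eps1_rate / 2``
and the resultants follow from the relaxation kernels.

Sign conventions: positive internal pressure gives positive resultants and
negative charge; axial compression (negative eps1_rate) gives positive
charge.  The library always returns signed charge.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy.special import expn as _expn_int
from scipy.special import gamma as _gamma
from scipy.special import gammaincc as _gammaincc
from scipy.special import hyp1f1 as _hyp1f1

from .kernels import relaxation_kernel_ohc
from .parameters import (
    ChargeTimeCourse,
    LoadingHistory,
    OHCMembraneParams,
    SphereMembraneParams,
)

__all__ = [
    "pressure_resultants",
    "pressure_coupling",
    "charge_step_pressure",
    "charge_ramp_pressure",
    "circumferential_rate",
    "resultant_rates_from_strain",
    "charge_ramp_strain",
    "generalized_expint",
    "charge_from_loading_convolution",
]

Params = OHCMembraneParams | SphereMembraneParams


def _check_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly positive and increasing")
    return t


def pressure_resultants(params: Params, dP: float) -> np.ndarray:
    """Membrane resultants (N/m) produced by internal pressure dP (Pa).

    Cylinder: ``(N1, N2) = (dP r_c / 2, dP r_c)``.
    Sphere: ``(N,) = (dP r_c / 2,)``.
    """
    if isinstance(params, OHCMembraneParams):
        return np.array([dP * params.r_c / 2.0, dP * params.r_c])
    return np.array([dP * params.r_c / 2.0])


def pressure_coupling(params: Params) -> float:
    """Combined coupling per unit pressure: sum_i a_i N_i / dP, C/(m^2 Pa).

    ``(a1/2 + a2) r_c`` for the cylinder, ``a r_c / 2`` for the sphere.
    """
    if isinstance(params, OHCMembraneParams):
        return (params.alpha1_Csp / 2.0 + params.alpha2_Csp) * params.r_c
    return params.alpha_Csp * params.r_c / 2.0


def charge_step_pressure(params: Params, dP0: float, t_grid) -> ChargeTimeCourse:
    """Charge per unit area after step pressure dP0 applied at t = 0.

    Closed form: ``q(t) = kappa dP0 (1 - exp(-t/tau_e))`` with ``kappa`` the
    geometry-dependent coupling of :func:`pressure_coupling`; the charge
    builds toward its steady value with characteristic time tau_e and is
    exactly linear in dP0.
    """
    t = _check_grid(t_grid)
    q = pressure_coupling(params) * dP0 * (1.0 - np.exp(-t / params.tau_e))
    return ChargeTimeCourse(t=t, q=q)


def charge_ramp_pressure(params: Params, P_r: float, t_grid) -> ChargeTimeCourse:
    """Charge per unit area under pressure applied at constant rate P_r.

    Closed form: ``q(t) = kappa P_r (t - tau_e (1 - exp(-t/tau_e)))``; an
    exponential transient followed by the constant-rate (time-linear) regime
    whose slope equals ``P_r`` times the per-unit-pressure steady charge of
    the step solution.
    """
    t = _check_grid(t_grid)
    tau = params.tau_e
    q = pressure_coupling(params) * P_r * (t - tau * (1.0 - np.exp(-t / tau)))
    return ChargeTimeCourse(t=t, q=q)


# ---------------------------------------------------------------------------
# Constant-rate axial strain (cylinder)
# ---------------------------------------------------------------------------

def circumferential_rate(eps1_rate: float) -> float:
    """Circumferential strain rate of a volume-conserving cylinder.

    First-order volume conservation, ``eps1 + 2 eps2 = 0``, gives
    ``eps2_rate = -eps1_rate / 2``.  Isolated here so that a different
    incompressibility relation can be substituted in one place.
    """
    return -eps1_rate / 2.0


def resultant_rates_from_strain(
    params: OHCMembraneParams, eps1_rate: float, t
) -> np.ndarray:
    """Resultant rates (N/(m s)) under constant axial strain rate.

    For strain rates constant since t = 0 the hereditary integral collapses
    to ``Ndot_i(t) = E_ij(t) epsdot_j`` with the relaxation kernel E and the
    volume-conserving circumferential rate.  Returns shape ``(2,)`` for
    scalar t, else ``t.shape + (2,)``.
    """
    if not isinstance(params, OHCMembraneParams):
        raise TypeError("ramp-strain loading is defined for the cylindrical cell")
    eps_rates = np.array([eps1_rate, circumferential_rate(eps1_rate)])
    E = relaxation_kernel_ohc(params, t)  # (..., 2, 2); raises for t <= 0
    return E @ eps_rates


def _filtered_ramp(t: np.ndarray, tau_e: float) -> np.ndarray:
    """(1/tau_e) int_0^t exp(-(t-s)/tau_e) s ds = t - tau_e (1 - e^(-t/tau))."""
    return t - tau_e * (1.0 - np.exp(-t / tau_e))


def _filtered_power(t: np.ndarray, p: float, tau_e: float) -> np.ndarray:
    """(1/tau_e) int_0^t exp(-(t-s)/tau_e) s**p ds for p > -1.

    Evaluated as ``t^(p+1) / (tau_e (p+1)) * 1F1(1; p+2; -t/tau_e)``, the
    (real) confluent-hypergeometric closed form of the convolution; this is
    the analytic continuation to negative argument of the generalized
    exponential-integral representation.  Well behaved for all t > 0.
    """
    x = t / tau_e
    return t ** (p + 1.0) / (tau_e * (p + 1.0)) * _hyp1f1(1.0, p + 2.0, -x)


def charge_ramp_strain(
    params: OHCMembraneParams, eps1_rate: float, t_grid
) -> ChargeTimeCourse:
    """Charge per unit area under constant-rate axial strain of a cylinder.

    The resultants grow as ``N_i(s) = epsdot_j (C_ij s + eta s^(1-nu) /
    Gamma(2-nu))``; filtering through the RC charge-transfer kernel gives

        q(t) = eps1_rate * C_sp-scaled * ( A [t - tau_e(1 - e^(-t/tau_e))]
                                           + B Phi(t) )

    with ``A = a1 (C11 - C12/2) + a2 (C12 - C22/2)``,
    ``B = eta (a1 + a2) / (2 Gamma(2-nu))`` and ``Phi`` the filtered power
    ``s^(1-nu)`` (confluent-hypergeometric closed form).  The response shows
    a transient (nonlinear) regime of duration ~tau_e followed by a
    constant-rate regime; for axial compression (eps1_rate < 0) the charge
    is positive.
    """
    if not isinstance(params, OHCMembraneParams):
        raise TypeError("ramp-strain loading is defined for the cylindrical cell")
    if params.nu >= 1.0:
        raise ValueError("ramp-strain charge requires the power-law model (nu < 1)")
    t = _check_grid(t_grid)
    a1, a2 = params.alpha1_Csp, params.alpha2_Csp
    A = a1 * (params.C11 - params.C12 / 2.0) + a2 * (params.C12 - params.C22 / 2.0)
    B = params.eta * (a1 + a2) / (2.0 * _gamma(2.0 - params.nu))
    q = eps1_rate * (
        A * _filtered_ramp(t, params.tau_e)
        + B * _filtered_power(t, 1.0 - params.nu, params.tau_e)
    )
    return ChargeTimeCourse(t=t, q=q)


# ---------------------------------------------------------------------------
# Generalized exponential integral
# ---------------------------------------------------------------------------

def generalized_expint(nu: float, x: float) -> float:
    """Generalized exponential integral E_nu(x) = int_1^inf e^(-x u) u^(-nu) du.

    Supports real (including non-integer and negative) order ``nu`` and
    ``x > 0``, to relative accuracy ~1e-12.  For ``nu < 1`` it is evaluated
    through the upper incomplete gamma function,
    ``E_nu(x) = x^(nu-1) Gamma(1-nu, x)``; larger orders use the forward
    recurrence ``E_{s+1}(x) = (e^(-x) - x E_s(x)) / s``.
    """
    x = float(x)
    if not x > 0:
        raise ValueError("generalized_expint requires x > 0")
    nu = float(nu)
    if nu == round(nu) and nu >= 0:
        return float(_expn_int(int(round(nu)), x))
    if nu < 1.0:
        a = 1.0 - nu
        return float(x ** (nu - 1.0) * _gamma(a) * _gammaincc(a, x))
    # non-integer nu >= 1: recur up from the fractional base order in (0, 1)
    base = nu - math.floor(nu)
    val = generalized_expint(base, x)
    s = base
    emx = math.exp(-x)
    while s < nu - 0.5:
        val = (emx - x * val) / s
        s += 1.0
    return float(val)


# ---------------------------------------------------------------------------
# Brute-force convolution oracle
# ---------------------------------------------------------------------------

def _resultant_history(params: Params, loading: LoadingHistory):
    """Return N_i(s) as a callable s -> ndarray for the given loading."""
    if loading.kind == "step_pressure":
        N0 = pressure_resultants(params, loading.dP0)
        return lambda s: N0
    if loading.kind == "ramp_pressure":
        Nr = pressure_resultants(params, loading.P_r)
        return lambda s: Nr * s
    if loading.kind == "ramp_strain":
        if not isinstance(params, OHCMembraneParams):
            raise TypeError("ramp-strain loading is defined for the cylindrical cell")
        eps_rates = np.array(
            [loading.eps1_rate, circumferential_rate(loading.eps1_rate)]
        )
        C = params.elastic_matrix
        eta, nu = params.eta, params.nu
        g1m = _gamma(1.0 - nu)

        def N_of_s(s: float) -> np.ndarray:
            # cumulative integral of the relaxation kernel, entry-wise:
            # int_0^s E_ij(u) du, the singular power integrated by quadrature
            if eta == 0.0:
                visc = 0.0
            else:
                visc, _ = integrate.quad(
                    lambda u: eta * u ** (-nu) / g1m, 0.0, s, points=[0.0]
                )
            return (C * s + visc * np.ones((2, 2))) @ eps_rates

        return N_of_s
    raise ValueError(f"unknown loading kind {loading.kind!r}")


def charge_from_loading_convolution(
    params: Params, loading: LoadingHistory, t_grid
) -> ChargeTimeCourse:
    """Charge by direct numerical convolution (independent oracle).

    Evaluates ``q(t) = sum_i a_i (1/tau_e) int_0^t e^(-(t-s)/tau_e) N_i(s) ds``
    with adaptive quadrature, building the resultant history N_i(s) from the
    loading definition (for ramp strain, by quadrature of the relaxation
    kernel).  Slow; intended as a cross-check of the closed forms on coarse
    grids.
    """
    t = _check_grid(t_grid)
    tau = params.tau_e
    if isinstance(params, OHCMembraneParams):
        a = np.array([params.alpha1_Csp, params.alpha2_Csp])
    else:
        a = np.array([params.alpha_Csp])
    N_of_s = _resultant_history(params, loading)

    def integrand(s: float, tk: float) -> float:
        return math.exp(-(tk - s) / tau) * float(a @ np.atleast_1d(N_of_s(s)))

    q = np.empty_like(t)
    for k, tk in enumerate(t):
        val, _ = integrate.quad(
            integrand, 0.0, tk, args=(tk,), limit=200, epsabs=1e-16, epsrel=1e-10
        )
        q[k] = val / tau
    return ChargeTimeCourse(t=t, q=q)
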