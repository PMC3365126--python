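"""Domain types, default parameter sets, and JSON config I/O.

All quantities are SI internally: moduli in N/m, times in s, angular
frequency in rad/s, capacitance in F/m^2, charge density in C/m^2.
Configs may declare selected fields in convenience units (``us``, ``um``,
``kHz``) via a top-level ``"units"`` mapping; they are converted on load.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "OHCMembraneParams",
    "SphereMembraneParams",
    "LoadingHistory",
    "FrequencySweep",
    "ChargeTimeCourse",
    "default_ohc_params",
    "default_sphere_params",
    "hek_alpha_csp",
    "load_params",
    "dump_params",
    "citation",
    "CITATIONS",
]


class ValidationError(ValueError):
    """Raised when a parameter set or config violates an invariant.

    The offending field name is stored in :attr:`field_name`.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(field_name, message)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OHCMembraneParams:
    """Parameters of the cylindrical outer-hair-cell composite wall.

    Attributes
    ----------
    C11, C12, C22 : float
        Elastic moduli of the orthotropic wall, N/m.  The elastic matrix
        ``[[C11, C12], [C12, C22]]`` must be positive definite.
    eta : float
        Power-law (springpot) viscoelastic coefficient, N·s^nu/m.
    nu : float
        Power-law exponent, in (0, 1).  ``nu = 1`` is accepted only for the
        Kelvin-Voigt comparison mode.
    tau_e : float
        Prestin charge-transfer (RC) time, s.
    C_sp : float
        Specific membrane capacitance, F/m^2.
    alpha1_Csp, alpha2_Csp : float
        Electromechanical coupling products alpha_i * C_sp, strain per volt.
        Only the products enter the constitutive equations.
    r_c : float
        Cell radius, m.
    """

    C11: float
    C12: float
    C22: float
    eta: float
    nu: float
    tau_e: float
    C_sp: float
    alpha1_Csp: float
    alpha2_Csp: float
    r_c: float

    def __post_init__(self) -> None:
        _require(self.C11 > 0, "C11", "must be positive")
        _require(self.C22 > 0, "C22", "must be positive")
        _require(
            self.C11 * self.C22 - self.C12**2 > 0,
            "C12",
            "elastic matrix must be positive definite (C11*C22 - C12^2 > 0)",
        )
        _require(self.eta >= 0, "eta", "must be non-negative")
        _require(0 < self.nu <= 1, "nu", "must lie in (0, 1]")
        _require(self.tau_e > 0, "tau_e", "must be positive")
        _require(self.C_sp > 0, "C_sp", "must be positive")
        _require(self.r_c > 0, "r_c", "must be positive")

    @property
    def elastic_matrix(self) -> np.ndarray:
        """2x2 elastic modulus matrix, N/m."""
        return np.array([[self.C11, self.C12], [self.C12, self.C22]])

    @property
    def alpha_csp(self) -> np.ndarray:
        """Coupling products (alpha1*Csp, alpha2*Csp) as a vector, 1/V."""
        return np.array([self.alpha1_Csp, self.alpha2_Csp])

    def replace(self, **changes) -> "OHCMembraneParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SphereMembraneParams:
    """Parameters of an isotropic spherical prestin-transfected cell membrane.

    ``K`` is the area modulus (N/m); remaining fields as in
    :class:`OHCMembraneParams` with a single coupling product ``alpha_Csp``.
    """

    K: float
    eta: float
    nu: float
    tau_e: float
    C_sp: float
    alpha_Csp: float
    r_c: float

    def __post_init__(self) -> None:
        _require(self.K > 0, "K", "must be positive")
        _require(self.eta >= 0, "eta", "must be non-negative")
        _require(0 < self.nu <= 1, "nu", "must lie in (0, 1]")
        _require(self.tau_e > 0, "tau_e", "must be positive")
        _require(self.C_sp > 0, "C_sp", "must be positive")
        _require(self.r_c > 0, "r_c", "must be positive")

    def replace(self, **changes) -> "SphereMembraneParams":
        return dataclasses.replace(self, **changes)


_LOADING_KINDS = ("step_pressure", "ramp_pressure", "ramp_strain")


@dataclass(frozen=True)
class LoadingHistory:
    """A mechanical stimulus applied at t = 0 under voltage clamp.

    Exactly one of ``dP0`` (step pressure, Pa), ``P_r`` (pressure rate,
    Pa/s) or ``eps1_rate`` (axial strain rate, 1/s) must be given,
    consistent with ``kind``.  The circumferential strain rate of the
    ramp-strain loading is derived internally from volume conservation.
    """

    kind: str
    dP0: float | None = None
    P_r: float | None = None
    eps1_rate: float | None = None

    def __post_init__(self) -> None:
        _require(self.kind in _LOADING_KINDS, "kind", f"must be one of {_LOADING_KINDS}")
        provided = {
            "dP0": self.dP0,
            "P_r": self.P_r,
            "eps1_rate": self.eps1_rate,
        }
        expected = {
            "step_pressure": "dP0",
            "ramp_pressure": "P_r",
            "ramp_strain": "eps1_rate",
        }[self.kind]
        for name, value in provided.items():
            if name == expected:
                _require(value is not None, name, f"required for kind={self.kind}")
            else:
                _require(value is None, name, f"must be unset for kind={self.kind}")

    @property
    def magnitude(self) -> float:
        return {
            "step_pressure": self.dP0,
            "ramp_pressure": self.P_r,
            "ramp_strain": self.eps1_rate,
        }[self.kind]


@dataclass(frozen=True)
class FrequencySweep:
    """Angular frequencies with normalized force amplitude and phase."""

    omega: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        amplitude = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "amplitude", amplitude)
        if self.phase is not None:
            object.__setattr__(self, "phase", np.asarray(self.phase, dtype=float))
        _require(omega.ndim == 1 and omega.size > 0, "omega", "must be 1-D, non-empty")
        _require(bool(np.all(omega > 0)), "omega", "must be positive")
        _require(bool(np.all(np.diff(omega) > 0)), "omega", "must be strictly increasing")
        _require(amplitude.shape == omega.shape, "amplitude", "shape mismatch with omega")
        _require(bool(np.all(amplitude > 0)), "amplitude", "must be positive")
        if self.phase is not None:
            _require(self.phase.shape == omega.shape, "phase", "shape mismatch with omega")

    def __len__(self) -> int:
        return self.omega.size

    @property
    def freq_hz(self) -> np.ndarray:
        return self.omega / (2.0 * math.pi)


@dataclass(frozen=True)
class ChargeTimeCourse:
    """Time grid (s, strictly positive) with charge per unit area (C/m^2)."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)
        _require(t.ndim == 1 and t.size > 0, "t", "must be 1-D, non-empty")
        _require(bool(np.all(t > 0)), "t", "must be positive")
        _require(bool(np.all(np.diff(t) > 0)), "t", "must be strictly increasing")
        _require(q.shape == t.shape, "q", "shape mismatch with t")


# ---------------------------------------------------------------------------
# Default parameter sets
# ---------------------------------------------------------------------------

#: Source annotations for every numeric default, retrievable via citation().
CITATIONS: dict[str, str] = {
    "C11": "Reconstructed from prior orthotropic-wall stiffness estimates "
    "(Tolomeo & Steele 1995 J Acoust Soc Am; Iwasa & Adachi 1997 Biophys J; "
    "Spector et al. 1998); adopted by Roy, Brownell & Spector (2012) PLoS ONE "
    "7(5):e37667, Methods 'Summary of Model Parameters'.",
    "C12": "As C11: reconstructed orthotropic-wall off-diagonal modulus "
    "(Tolomeo & Steele 1995; Iwasa & Adachi 1997; Spector et al. 1998).",
    "C22": "As C11: reconstructed circumferential wall modulus "
    "(Tolomeo & Steele 1995; Iwasa & Adachi 1997; Spector et al. 1998).",
    "eta": "Calibrated in this package so that the power-law model with "
    "nu = 0.7 yields the near-frequency-invariant normalized isometric force "
    "over 1-80 kHz reported by Roy, Brownell & Spector (2012), Results "
    "(best fit to the Frank et al. 1999 PNAS microchamber data).",
    "nu": "Roy, Brownell & Spector (2012) PLoS ONE 7(5):e37667, Results: "
    "'The obtained power of 0.7'.",
    "tau_e": "Roy, Brownell & Spector (2012), Methods: best RC-filter fit to "
    "the Fokker-Planck charge-transfer solution, tau_e = 5 us.",
    "C_sp": "Standard biological membrane specific capacitance, 1 uF/cm^2 "
    "(= 0.01 F/m^2); e.g. Hille, Ion Channels of Excitable Membranes.",
    "alpha1_Csp": "Reconstructed from microchamber electromotile length "
    "changes (Dallos et al. 1991 Science; Tolomeo & Steele 1995): axial "
    "active strain per volt, negative for depolarization-driven shortening.",
    "alpha2_Csp": "Reconstructed from microchamber electromotile radius "
    "changes (Hallworth et al. 1993 J Neurophysiol; Tolomeo & Steele 1995): "
    "circumferential active strain per volt, opposite sign and smaller "
    "magnitude than the axial product.",
    "r_c": "Typical outer hair cell radius, ~5 um (Brownell et al. 1985 "
    "Science; standard OHC morphometry).",
    "K": "Rawicz et al. (2000) Biophys J 79:328: area modulus of the plasma "
    "membrane, K = 0.24 N/m; used by Roy, Brownell & Spector (2012), Methods.",
    "alpha_Csp": "Roy, Brownell & Spector (2012), Methods: HEK-cell data "
    "(Zheng et al. 2000 Nature): ~0.4 V potential change displaces the "
    "membrane by about -0.1 um for a ~5 um radius; alpha*Csp = "
    "(displacement/radius)/deltaV = -0.05 1/V (see hek_alpha_csp).",
}


def citation(field_name: str) -> str:
    """Return the source annotation for a default numeric parameter."""
    return CITATIONS[field_name]


def hek_alpha_csp(
    displacement: float = -0.1e-6,
    radius: float = 5.0e-6,
    delta_v: float = 0.4,
) -> float:
    """Coupling product alpha*Csp for the spherical (HEK-type) cell.

    Computed as (displacement/radius)/delta_v from the reported steady-state
    electromotile response: a potential change of ~0.4 V displaces the
    membrane by about -0.1 um for a cell radius of about 5 um.
    """
    return (displacement / radius) / delta_v


# eta is calibrated (see CITATIONS["eta"]) so the power-law force stays flat
# over 1-80 kHz; value frozen by scripts/calibrate_eta.py.
_DEFAULT_ETA = 1.1e-5  # N s^nu / m


def default_ohc_params() -> OHCMembraneParams:
    """The default (optimal) outer-hair-cell parameter set.

    Every numeric value carries a source annotation retrievable through
    :func:`citation`.
    """
    return OHCMembraneParams(
        C11=0.075,
        C12=0.07,
        C22=0.19,
        eta=_DEFAULT_ETA,
        nu=0.7,
        tau_e=5.0e-6,
        C_sp=0.01,
        alpha1_Csp=-0.10,
        alpha2_Csp=0.03,
        r_c=5.0e-6,
    )


def default_sphere_params() -> SphereMembraneParams:
    """The default parameter set for a spherical prestin-transfected cell."""
    return SphereMembraneParams(
        K=0.24,
        eta=_DEFAULT_ETA,
        nu=0.7,
        tau_e=5.0e-6,
        C_sp=0.01,
        alpha_Csp=hek_alpha_csp(),
        r_c=5.0e-6,
    )


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

# Multiplicative factors to SI for the optional "units" declarations.
_UNIT_FACTORS = {
    "s": 1.0,
    "ms": 1e-3,
    "us": 1e-6,
    "m": 1.0,
    "um": 1e-6,
    "hz": 2.0 * math.pi,  # frequency declared in Hz -> rad/s
    "khz": 2.0 * math.pi * 1e3,
    "si": 1.0,
}

_MECH_FIELDS_CYL = ("C11", "C12", "C22", "eta", "nu", "r_c")
_MECH_FIELDS_SPH = ("K", "eta", "nu", "r_c")
_ELEC_FIELDS = ("tau_e", "C_sp")


def _convert(value: float, field_name: str, units: dict[str, str]) -> float:
    unit = units.get(field_name)
    if unit is None:
        return value
    key = unit.lower()
    if key not in _UNIT_FACTORS:
        raise ValidationError(field_name, f"unknown unit {unit!r}")
    return value * _UNIT_FACTORS[key]


def _section(cfg: dict, name: str) -> dict:
    if name not in cfg or not isinstance(cfg[name], dict):
        raise ValidationError(name, "missing config section")
    return cfg[name]


def _pull(section: dict, section_name: str, field_name: str, units: dict) -> float:
    if field_name not in section:
        raise ValidationError(field_name, f"missing from {section_name!r} section")
    value = section[field_name]
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValidationError(field_name, "must be a number")
    return _convert(float(value), field_name, units)


def load_params(config_path: str | Path) -> OHCMembraneParams | SphereMembraneParams:
    """Load and validate a parameter config (JSON).

    Schema: top-level ``"geometry"`` ("cylinder" | "sphere") plus
    ``"mechanical"``, ``"electrical"`` and ``"coupling"`` sections; an
    optional ``"units"`` mapping declares non-SI units for single fields.
    """
    path = Path(config_path)
    with open(path) as fh:
        cfg = json.load(fh)
    return params_from_dict(cfg)


def params_from_dict(cfg: dict) -> OHCMembraneParams | SphereMembraneParams:
    geometry = cfg.get("geometry")
    if geometry not in ("cylinder", "sphere"):
        raise ValidationError("geometry", "must be 'cylinder' or 'sphere'")
    units = cfg.get("units", {})
    mech = _section(cfg, "mechanical")
    elec = _section(cfg, "electrical")
    coup = _section(cfg, "coupling")
    common = dict(
        eta=_pull(mech, "mechanical", "eta", units),
        nu=_pull(mech, "mechanical", "nu", units),
        r_c=_pull(mech, "mechanical", "r_c", units),
        tau_e=_pull(elec, "electrical", "tau_e", units),
        C_sp=_pull(elec, "electrical", "C_sp", units),
    )
    if geometry == "cylinder":
        return OHCMembraneParams(
            C11=_pull(mech, "mechanical", "C11", units),
            C12=_pull(mech, "mechanical", "C12", units),
            C22=_pull(mech, "mechanical", "C22", units),
            alpha1_Csp=_pull(coup, "coupling", "alpha1_Csp", units),
            alpha2_Csp=_pull(coup, "coupling", "alpha2_Csp", units),
            **common,
        )
    return SphereMembraneParams(
        K=_pull(mech, "mechanical", "K", units),
        alpha_Csp=_pull(coup, "coupling", "alpha_Csp", units),
        **common,
    )


def params_to_dict(params: OHCMembraneParams | SphereMembraneParams) -> dict:
    """Serialize a parameter object to the documented config schema (SI)."""
    if isinstance(params, OHCMembraneParams):
        return {
            "geometry": "cylinder",
            "mechanical": {
                "C11": params.C11,
                "C12": params.C12,
                "C22": params.C22,
                "eta": params.eta,
                "nu": params.nu,
                "r_c": params.r_c,
            },
            "electrical": {"tau_e": params.tau_e, "C_sp": params.C_sp},
            "coupling": {
                "alpha1_Csp": params.alpha1_Csp,
                "alpha2_Csp": params.alpha2_Csp,
            },
        }
    if isinstance(params, SphereMembraneParams):
        return {
            "geometry": "sphere",
            "mechanical": {
                "K": params.K,
                "eta": params.eta,
                "nu": params.nu,
                "r_c": params.r_c,
            },
            "electrical": {"tau_e": params.tau_e, "C_sp": params.C_sp},
            "coupling": {"alpha_Csp": params.alpha_Csp},
        }
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def dump_params(params: OHCMembraneParams | SphereMembraneParams, path: str | Path) -> Path:
    """Write a parameter object as a JSON config; round-trips via load_params."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(params_to_dict(params), fh, indent=2)
        fh.write("\n")
    return path
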