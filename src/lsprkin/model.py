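"""Core domain types and the closed-form 1:1 pseudo-first-order binding model.

The binding of a polycation P to an immobilized polyanion Pa (or vice versa)
is treated as a bimolecular association

    P + Pa  <-- k_off / k_on -->  P-Pa

under pseudo-first-order conditions: the analyte is continuously flowed over
the surface, so its chain concentration [P]_0 stays constant and the rate law
integrates to a single-exponential approach to equilibrium,

    R(t) = R_eq * (1 - exp(-k_obs * t)),      k_obs = k_on*[P]_0 + k_off,
    R_eq = R_max * [P]_0 / ([P]_0 + K_D),     K_D  = k_off / k_on.

Concentrations on the chain ("polymeric") basis are in uM throughout this
module; k_on is per-uM per-second, k_off per-second.  The instrument response
unit (RU) is proportional to bound mass, ~0.1 pg per RU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DomainError

#: picograms of bound mass per response unit (1000 RU ~ 100 pg)
PG_PER_RU = 0.1


@dataclass(frozen=True)
class PolymerSpec:
    """A polyelectrolyte, described by its repeat unit and (optionally) chain mass.

    Parameters
    ----------
    name : str
        Free-text label, e.g. ``"PEI"``.
    repeat_unit_mass : float
        Molar mass M_o of one repeat unit, g/mol.
    chain_mass : float, optional
        Number-average molecular weight M_n, g/mol.  Absent for the polymer
        whose M_n the analysis is meant to determine.
    """

    name: str
    repeat_unit_mass: float
    chain_mass: Optional[float] = None

    def __post_init__(self):
        if not self.repeat_unit_mass > 0:
            raise DomainError(f"repeat_unit_mass must be > 0, got {self.repeat_unit_mass}")
        if self.chain_mass is not None and self.chain_mass < self.repeat_unit_mass:
            raise DomainError(
                f"chain_mass {self.chain_mass} < repeat_unit_mass {self.repeat_unit_mass}"
            )

    @property
    def degree_of_polymerization(self) -> float:
        """DP = M_n / M_o; requires chain_mass."""
        if self.chain_mass is None:
            raise DomainError(f"polymer {self.name!r} has no chain_mass (M_n)")
        return self.chain_mass / self.repeat_unit_mass


@dataclass(frozen=True)
class KineticParams:
    """Association/dissociation rate constants of the 1:1 complex (chain basis).

    k_on is per-uM per-second, k_off per-second; standard errors optional.
    """

    k_on: float
    k_off: float
    se_k_on: Optional[float] = None
    se_k_off: Optional[float] = None

    def __post_init__(self):
        if not self.k_on > 0:
            raise DomainError(f"k_on must be > 0, got {self.k_on}")
        if self.k_off < 0:
            raise DomainError(f"k_off must be >= 0, got {self.k_off}")
        for nm in ("se_k_on", "se_k_off"):
            v = getattr(self, nm)
            if v is not None and v < 0:
                raise DomainError(f"{nm} must be >= 0, got {v}")

    @property
    def dissociation_constant_uM(self) -> float:
        """K_D = k_off / k_on, in uM."""
        return self.k_off / self.k_on


@dataclass
class Sensorgram:
    """Dual-channel biosensor time series with injection metadata.

    ``time`` is in seconds on a strictly increasing grid; responses are in RU.
    The reference channel, when present, carries the bulk refractive-index
    shift but no binding and is used for correction.
    """

    time: np.ndarray
    response_active: np.ndarray
    injection_start: float
    injection_end: float
    response_reference: Optional[np.ndarray] = None
    analyte: Optional[PolymerSpec] = None
    monomeric_concentration_mM: Optional[float] = None
    flow_rate_uL_min: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response_active = np.asarray(self.response_active, dtype=float)
        if self.time.ndim != 1:
            raise DomainError("time must be one-dimensional")
        if np.any(np.diff(self.time) <= 0):
            bad = int(np.argmax(np.diff(self.time) <= 0)) + 1
            raise DomainError(f"time must be strictly increasing (violation at index {bad})")
        if self.response_active.shape != self.time.shape:
            raise DomainError("response_active length differs from time")
        if self.response_reference is not None:
            self.response_reference = np.asarray(self.response_reference, dtype=float)
            if self.response_reference.shape != self.time.shape:
                raise DomainError("response_reference length differs from time")
        if not self.injection_start < self.injection_end:
            raise DomainError("injection_start must precede injection_end")
        if self.injection_end > self.time[-1] + 1e-12:
            raise DomainError("injection_end lies beyond the last sample")

    @property
    def has_reference(self) -> bool:
        return self.response_reference is not None


def observed_rate(conc_polymeric_uM, params: KineticParams):
    """Observed pseudo-first-order rate constant, k_obs = k_on*C + k_off (1/s).

    ``conc_polymeric_uM`` is the chain concentration in uM; scalar or array.
    """
    c = np.asarray(conc_polymeric_uM, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be non-negative")
    out = params.k_on * c + params.k_off
    return float(out) if out.ndim == 0 else out


def equilibrium_response(conc_polymeric_uM, params: KineticParams, r_max: float):
    """Equilibrium amplitude R_eq = R_max * C / (C + K_D), in RU."""
    c = np.asarray(conc_polymeric_uM, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be non-negative")
    if not r_max > 0:
        raise DomainError("r_max must be > 0")
    kd = params.dissociation_constant_uM
    with np.errstate(invalid="ignore"):
        out = np.where(c + kd > 0, r_max * c / (c + kd), 0.0)
    return float(out) if out.ndim == 0 else out


def association_response(t, conc_polymeric_uM, params: KineticParams, r_max: float):
    """Association-phase response R(t) = R_eq*(1 - exp(-k_obs*t)), in RU.

    ``t`` is seconds since injection start; scalar or array, must be >= 0.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise DomainError("t must be non-negative")
    k = observed_rate(conc_polymeric_uM, params)
    req = equilibrium_response(conc_polymeric_uM, params, r_max)
    out = req * -np.expm1(-np.asarray(k) * tt)
    return float(out) if out.ndim == 0 else out


def dissociation_response(t_since_end, r_end: float, k_off: float):
    """Dissociation-phase response r_end * exp(-k_off * t), in RU."""
    tt = np.asarray(t_since_end, dtype=float)
    if np.any(tt < 0):
        raise DomainError("t_since_end must be non-negative")
    if k_off < 0:
        raise DomainError("k_off must be >= 0")
    out = r_end * np.exp(-k_off * tt)
    return float(out) if out.ndim == 0 else out


def ru_to_mass(response_ru):
    """Convert response units to bound mass in picograms (0.1 pg per RU)."""
    out = np.asarray(response_ru, dtype=float) * PG_PER_RU
    return float(out) if out.ndim == 0 else out
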