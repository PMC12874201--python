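"""Concentration-basis conversion and calibration-free M_n determination.

A polymer solution prepared by repeat-unit molarity ("monomeric", mM) is
converted to chain molarity ("polymeric", uM) by dividing by the degree of
polymerization DP = M_n/M_o.  When one binding partner's M_n is unknown, the
symmetric-k_on relation closes the system: the intrinsic chain association
rate k_on is the same whichever partner is immobilized, so the slope alpha
of k_obs versus the unknown polymer's *monomeric* concentration satisfies

    alpha = k_on / DP      =>      DP = k_on / alpha,   M_n = DP * M_o.

k_on comes from the known partner's polymeric-basis rate line, alpha from
the unknown partner's monomeric-basis line.  Uncertainty is propagated to
first order (delta method) assuming the two slopes are independent — they
come from separate experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import BasisError, DomainError
from .model import PolymerSpec
from .regression import RateLine


def degree_of_polymerization(polymer: PolymerSpec) -> float:
    """DP = M_n / M_o; requires the polymer's chain mass."""
    return polymer.degree_of_polymerization


def monomeric_to_polymeric(conc_mM: float, polymer: PolymerSpec) -> float:
    """Convert a monomeric concentration (mM) to chain concentration (uM).

    [Polymeric] = [Monomeric] * M_o / M_n = [Monomeric] / DP, with the
    mM -> uM factor of 1000 applied.
    """
    if conc_mM < 0:
        raise DomainError("concentration must be non-negative")
    return conc_mM * 1000.0 / polymer.degree_of_polymerization


def polymeric_to_monomeric(conc_uM: float, polymer: PolymerSpec) -> float:
    """Inverse of :func:`monomeric_to_polymeric`: chain uM back to monomeric mM."""
    if conc_uM < 0:
        raise DomainError("concentration must be non-negative")
    return conc_uM * polymer.degree_of_polymerization / 1000.0


def solve_dp(k_on: float, alpha: float) -> float:
    """DP = k_on / alpha.

    Both rates must be on the per-uM basis: k_on per uM (chain), alpha per
    uM (monomeric).
    """
    if not k_on > 0:
        raise DomainError("k_on must be positive")
    if not alpha > 0:
        raise DomainError("alpha must be positive")
    return k_on / alpha


def solve_mn(dp: float, repeat_unit_mass: float) -> float:
    """M_n = DP * M_o, g/mol.  Warns if DP < 1 (sub-monomer chain)."""
    if not repeat_unit_mass > 0:
        raise DomainError("repeat_unit_mass must be positive")
    if dp < 1:
        warnings.warn(f"DP = {dp:.3g} < 1 is unphysical for a polymer", stacklevel=2)
    return dp * repeat_unit_mass


def propagate_mn_uncertainty(
    k_on: float, se_k_on: float, alpha: float, se_alpha: float, repeat_unit_mass: float
) -> tuple[float, float]:
    """First-order SEs of (DP, M_n) from independent k_on and alpha.

    se_DP/DP = sqrt((se_kon/k_on)^2 + (se_alpha/alpha)^2); se_Mn = M_o*se_DP.
    """
    if se_k_on < 0 or se_alpha < 0:
        raise DomainError("standard errors must be non-negative")
    dp = solve_dp(k_on, alpha)
    rel = np.hypot(se_k_on / k_on, se_alpha / alpha)
    se_dp = dp * float(rel)
    return se_dp, se_dp * repeat_unit_mass


@dataclass(frozen=True)
class MnResult:
    """Degree of polymerization and number-average molecular weight.

    ``dp``/``mn`` are the exact solved values (mn = dp * M_o identically);
    ``dp_reported``/``mn_reported`` follow the reporting convention of the
    field: DP to the nearest integer, M_n = round(DP)*M_o to the nearest
    100 g/mol.
    """

    dp: float
    mn: float
    k_on_used: float
    alpha_used: float  # per-uM-monomeric per-second
    repeat_unit_mass: float
    se_dp: Optional[float] = None
    se_mn: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.mn - self.dp * self.repeat_unit_mass) > 1e-6 * max(self.mn, 1.0):
            raise DomainError("mn must equal dp * repeat_unit_mass")

    @property
    def dp_reported(self) -> int:
        return int(round(self.dp))

    @property
    def mn_reported(self) -> float:
        return round(self.dp_reported * self.repeat_unit_mass / 100.0) * 100.0


def alpha_per_uM(line: RateLine) -> float:
    """Slope of a monomeric-basis rate line converted to per-uM units."""
    if line.basis != "monomeric_mM":
        raise BasisError("alpha must come from a monomeric-basis (mM) rate line")
    return line.slope / 1000.0  # per-mM -> per-uM


def estimate_mn(
    known_line: RateLine,
    unknown_line: RateLine,
    unknown_polymer: PolymerSpec,
    provenance: Optional[dict] = None,
) -> MnResult:
    """Solve DP and M_n of the unknown polymer from the two rate lines.

    ``known_line`` must be on the polymeric uM basis (its slope is k_on);
    ``unknown_line`` on the monomeric mM basis (its slope is 1000*alpha).
    """
    if known_line.basis != "polymeric_uM":
        raise BasisError("known-polymer line must be on the polymeric uM basis")
    k_on = known_line.slope
    alpha = alpha_per_uM(unknown_line)
    dp = solve_dp(k_on, alpha)
    mn = solve_mn(dp, unknown_polymer.repeat_unit_mass)
    se_dp, se_mn = propagate_mn_uncertainty(
        k_on, known_line.se_slope, alpha, unknown_line.se_slope / 1000.0,
        unknown_polymer.repeat_unit_mass,
    )
    return MnResult(
        dp=dp,
        mn=mn,
        k_on_used=k_on,
        alpha_used=alpha,
        repeat_unit_mass=unknown_polymer.repeat_unit_mass,
        se_dp=se_dp,
        se_mn=se_mn,
        provenance=provenance or {},
    )
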