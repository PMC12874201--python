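"""Linear regression of k_obs against analyte concentration.

Under the pseudo-first-order model k_obs is affine in the chain
concentration: k_obs = k_on*[P]_0 + k_off.  A straight-line fit of k_obs
versus [P]_0 therefore yields k_on as the slope and k_off as the intercept,
and K_D = k_off/k_on follows.  On the monomeric basis the slope is
alpha = k_on/DP instead, which is what the molecular-weight solver consumes.

The estimator computes the (optionally weighted) least-squares solution in
closed form from the normal equations, with classical OLS standard errors
(residual variance on n-2 degrees of freedom).  Unweighted OLS on
replicate-mean k_obs is the default procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import BasisError, DomainError
from .model import KineticParams

#: allowed concentration bases for a RateLine
BASES = ("polymeric_uM", "monomeric_mM")


class RateLineRegression(RegressorMixin, BaseEstimator):
    """Straight-line fit y = slope*x + intercept by (weighted) least squares.

    ``X`` is the concentration vector (shape (n,) or (n, 1)), ``y`` the
    observed rates; optional per-point ``sample_weight`` gives weighted least
    squares (e.g. inverse-variance from replicate SEMs).

    Attributes
    ----------
    slope_, intercept_ : line coefficients.
    se_slope_, se_intercept_ : classical standard errors (n-2 df).
    r_squared_ : coefficient of determination (weighted when weights given).
    n_ : number of points.
    """

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise DomainError("X must be 1-D or a single column")
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise DomainError("X and y must have the same length")
        n = x.size
        if n < 3:
            raise DomainError(f"need >= 3 points for a rate line, got {n}")
        if np.ptp(x) == 0:
            raise DomainError("degenerate design: all concentrations equal")
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != x.shape or np.any(w <= 0):
                raise DomainError("weights must be positive, one per point")

        # weighted normal equations for [intercept, slope]
        sw = w.sum()
        xbar = float(np.sum(w * x) / sw)
        ybar = float(np.sum(w * y) / sw)
        sxx = float(np.sum(w * (x - xbar) ** 2))
        sxy = float(np.sum(w * (x - xbar) * (y - ybar)))
        slope = sxy / sxx
        intercept = ybar - slope * xbar

        resid = y - (intercept + slope * x)
        s2 = float(np.sum(w * resid**2)) / (n - 2)
        self.se_slope_ = float(np.sqrt(s2 / sxx))
        self.se_intercept_ = float(np.sqrt(s2 * (1.0 / sw + xbar**2 / sxx)))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        self.r_squared_ = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 0.0
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.residuals_ = resid
        self.n_ = n
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return self.intercept_ + self.slope_ * x


@dataclass(frozen=True)
class RateLine:
    """Fitted k_obs-vs-concentration line with its concentration basis.

    ``basis`` is ``"polymeric_uM"`` (chain concentration, uM — slope is k_on)
    or ``"monomeric_mM"`` (repeat-unit concentration, mM — slope is alpha
    per mM).
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    basis: str
    n_points: int

    def __post_init__(self):
        if self.basis not in BASES:
            raise BasisError(f"basis must be one of {BASES}, got {self.basis!r}")
        if self.n_points < 3:
            raise DomainError("a rate line needs >= 3 points")


def fit_rate_line(
    concs: Sequence[float],
    kobs: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    basis: str = "polymeric_uM",
) -> RateLine:
    """Fit k_obs = slope*conc + intercept and record the concentration basis."""
    est = RateLineRegression().fit(np.asarray(concs, float), np.asarray(kobs, float),
                                   sample_weight=weights)
    return RateLine(
        slope=est.slope_,
        intercept=est.intercept_,
        se_slope=est.se_slope_,
        se_intercept=est.se_intercept_,
        r_squared=est.r_squared_,
        basis=basis,
        n_points=est.n_,
    )


def kinetic_params_from_line(line: RateLine) -> KineticParams:
    """Interpret a polymeric-basis rate line as (k_on, k_off).

    A negative intercept is clamped to k_off = 0 with a warning (a rate
    cannot be negative); the raw intercept remains available on the line.
    """
    if line.basis != "polymeric_uM":
        raise BasisError(
            "rate line is on the monomeric basis; convert concentrations to "
            "polymeric uM before extracting k_on/k_off"
        )
    k_off = line.intercept
    if k_off < 0:
        warnings.warn(
            f"negative intercept {k_off:.4g} 1/s clamped to k_off = 0", stacklevel=2
        )
        k_off = 0.0
    return KineticParams(
        k_on=line.slope, k_off=k_off, se_k_on=line.se_slope, se_k_off=line.se_intercept
    )


def dissociation_constant_nM(params: KineticParams) -> float:
    """Equilibrium dissociation constant K_D = k_off/k_on, in nM."""
    if not params.k_on > 0:
        raise DomainError("k_on must be positive")
    return params.k_off / params.k_on * 1e3  # uM -> nM


@dataclass(frozen=True)
class LinearityReport:
    """Simple linear-regression summary for e.g. stepwise multilayer buildup."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def linearity_check(x: Sequence[float], y: Sequence[float]) -> LinearityReport:
    """R² and slope of a simple linear regression (e.g. bilayer index vs RU)."""
    est = RateLineRegression().fit(np.asarray(x, float), np.asarray(y, float))
    return LinearityReport(
        slope=est.slope_, intercept=est.intercept_,
        r_squared=est.r_squared_, n_points=est.n_,
    )
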