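"""Exponential association fitting: extract k_obs from transients.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore), so they compose with sklearn pipelines and model selection.
``X`` is the time vector (seconds, shape (n,) or (n, 1)), ``y`` the response
in RU.  Thin module-level functions (:func:`fit_one_phase`,
:func:`fit_two_phase`) wrap the estimators for pipeline use on
:class:`~lsprkin.preprocess.Transient` objects.

Models
------
one-phase :   R(t) = C * (1 - exp(-k_obs t))            [+ offset]
two-phase :   R(t) = A_f (1 - exp(-k_f t)) + A_s (1 - exp(-k_s t))

The two-phase model is canonicalized so k_fast >= k_slow.  When the two
rates collapse or an amplitude vanishes the fit is flagged degenerate; on
outright non-convergence :func:`fit_two_phase` falls back, reportably, to
the one-phase model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DegenerateDataError, DomainError, FitConvergenceError
from .preprocess import Transient


def _as_time(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise DomainError("X must be a 1-D time vector or a single-column matrix")
    if np.any(t < 0):
        raise DomainError("times must be non-negative")
    return t


def _data_key(t: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(t).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()


def _k_init(t: np.ndarray, y: np.ndarray) -> float:
    """1/t63 heuristic: t63 is the first time the response exceeds 63.2% of max."""
    c0 = float(np.max(y))
    above = np.nonzero(y >= 0.632 * c0)[0]
    if above.size and t[above[0]] > 0:
        return 1.0 / float(t[above[0]])
    return 3.0 / float(t[-1])  # fall back: assume ~95% equilibration over the record


def _solve(residual, x0, bounds, tol, max_iter):
    res = least_squares(
        residual, x0, bounds=bounds, ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter
    )
    if res.status <= 0:
        raise FitConvergenceError(
            "least-squares did not converge",
            details={"nfev": res.nfev, "cost": res.cost, "status": res.status},
        )
    return res


def _covariance(res, n: int):
    """Parameter covariance from the Jacobian at the solution; None if singular."""
    J = res.jac
    p = J.shape[1]
    if n <= p:
        return None
    try:
        jtj_inv = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None
    s2 = 2.0 * res.cost / (n - p)
    return s2 * jtj_inv


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


class OnePhaseAssociation(RegressorMixin, BaseEstimator):
    """One-phase exponential association model, R(t) = C(1 - e^{-k_obs t}).

    Parameters
    ----------
    free_offset : bool, default False
        Fit an additive offset.  Off by default: preprocessing zeroes the
        baseline and the model passes through the origin.
    k_bounds : tuple, default (1e-6, 10.0)
        Bounds on k_obs, 1/s.
    tol : float, default 1e-10
        Convergence tolerance on the cost function.
    max_iter : int, default 1000
        Maximum function evaluations.

    Attributes
    ----------
    k_obs_, se_k_obs_ : observed rate constant (1/s) and its standard error.
    plateau_, se_plateau_ : equilibrium amplitude C (RU) and SE.
    offset_ : fitted offset (0 unless ``free_offset``).
    r_squared_ : 1 - SS_res/SS_tot about the mean.
    residuals_ : per-point residuals y - model, RU.
    n_iter_ : function evaluations used.
    """

    def __init__(self, free_offset: bool = False, k_bounds=(1e-6, 10.0),
                 tol: float = 1e-10, max_iter: int = 1000):
        self.free_offset = free_offset
        self.k_bounds = k_bounds
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        t = _as_time(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise DomainError("X and y must have the same length")
        if t.size < 5:
            raise DomainError(f"need >= 5 samples, got {t.size}")
        if np.ptp(y) == 0:
            raise DegenerateDataError("response is constant; no rate information")

        c0 = max(float(np.max(y)), 1e-9)
        k0 = float(np.clip(_k_init(t, y), *self.k_bounds))

        if self.free_offset:
            def residual(p):
                return p[0] * -np.expm1(-p[1] * t) + p[2] - y
            x0 = [c0, k0, 0.0]
            lb = [1e-12, self.k_bounds[0], -np.inf]
            ub = [np.inf, self.k_bounds[1], np.inf]
        else:
            def residual(p):
                return p[0] * -np.expm1(-p[1] * t) - y
            x0 = [c0, k0]
            lb = [1e-12, self.k_bounds[0]]
            ub = [np.inf, self.k_bounds[1]]

        res = _solve(residual, x0, (lb, ub), self.tol, self.max_iter)
        cov = _covariance(res, t.size)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)) if cov is not None else [np.nan] * len(x0)

        self.plateau_ = float(res.x[0])
        self.k_obs_ = float(res.x[1])
        self.offset_ = float(res.x[2]) if self.free_offset else 0.0
        self.se_plateau_ = float(se[0])
        self.se_k_obs_ = float(se[1])
        self.residuals_ = -res.fun  # y - model
        self.r_squared_ = _r_squared(y, res.fun)
        self.n_iter_ = int(res.nfev)
        self.data_key_ = _data_key(t, y)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = _as_time(X)
        return self.plateau_ * -np.expm1(-self.k_obs_ * t) + self.offset_


class TwoPhaseAssociation(RegressorMixin, BaseEstimator):
    """Two-phase exponential association, A_f(1-e^{-k_f t}) + A_s(1-e^{-k_s t}).

    Canonicalized so ``k_fast_ >= k_slow_``.  ``degenerate_`` is set when the
    two rates are indistinguishable or an amplitude vanishes, i.e. the data
    do not support a second phase.
    """

    def __init__(self, k_bounds=(1e-6, 10.0), tol: float = 1e-10, max_iter: int = 2000):
        self.k_bounds = k_bounds
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        t = _as_time(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise DomainError("X and y must have the same length")
        if t.size < 7:
            raise DomainError(f"need >= 7 samples for a two-phase fit, got {t.size}")
        if np.ptp(y) == 0:
            raise DegenerateDataError("response is constant; no rate information")

        c0 = max(float(np.max(y)), 1e-9)
        k0 = _k_init(t, y)
        lo, hi = self.k_bounds
        x0 = [c0 / 2, float(np.clip(3 * k0, lo, hi)),
              c0 / 2, float(np.clip(0.3 * k0, lo, hi))]
        lb = [0.0, lo, 0.0, lo]
        ub = [np.inf, hi, np.inf, hi]

        def residual(p):
            return p[0] * -np.expm1(-p[1] * t) + p[2] * -np.expm1(-p[3] * t) - y

        res = _solve(residual, x0, (lb, ub), self.tol, self.max_iter)
        a_f, k_f, a_s, k_s = res.x
        cov = _covariance(res, t.size)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)) if cov is not None else [np.nan] * 4
        if k_f < k_s:  # canonical ordering
            a_f, k_f, a_s, k_s = a_s, k_s, a_f, k_f
            se = [se[2], se[3], se[0], se[1]]

        self.a_fast_, self.k_fast_ = float(a_f), float(k_f)
        self.a_slow_, self.k_slow_ = float(a_s), float(k_s)
        self.se_a_fast_, self.se_k_fast_ = float(se[0]), float(se[1])
        self.se_a_slow_, self.se_k_slow_ = float(se[2]), float(se[3])
        total = self.a_fast_ + self.a_slow_
        self.degenerate_ = bool(
            self.k_fast_ <= 1.05 * self.k_slow_
            or (total > 0 and min(self.a_fast_, self.a_slow_) < 1e-3 * total)
        )
        self.residuals_ = -res.fun
        self.r_squared_ = _r_squared(y, res.fun)
        self.n_iter_ = int(res.nfev)
        self.data_key_ = _data_key(t, y)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = _as_time(X)
        return (self.a_fast_ * -np.expm1(-self.k_fast_ * t)
                + self.a_slow_ * -np.expm1(-self.k_slow_ * t))


@dataclass
class TransientFit:
    """Result of fitting one association transient."""

    model: str  # "one_phase" | "two_phase"
    plateau: float
    r_squared: float
    residuals: np.ndarray
    n_points: int
    n_iter: int
    data_key: str
    k_obs: Optional[float] = None
    se_k_obs: Optional[float] = None
    se_plateau: Optional[float] = None
    offset: float = 0.0
    k_fast: Optional[float] = None
    k_slow: Optional[float] = None
    a_fast: Optional[float] = None
    a_slow: Optional[float] = None
    degenerate: bool = False
    fallback: bool = False
    conc_monomeric_mM: Optional[float] = None
    source: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        if self.model == "two_phase":
            return 4
        return 3 if self.offset != 0.0 else 2


def fit_one_phase(tr: Transient, free_offset: bool = False) -> TransientFit:
    """Fit the one-phase exponential binding model to a transient."""
    est = OnePhaseAssociation(free_offset=free_offset).fit(tr.time, tr.response)
    return TransientFit(
        model="one_phase",
        k_obs=est.k_obs_,
        se_k_obs=est.se_k_obs_,
        plateau=est.plateau_,
        se_plateau=est.se_plateau_,
        offset=est.offset_,
        r_squared=est.r_squared_,
        residuals=est.residuals_,
        n_points=tr.time.size,
        n_iter=est.n_iter_,
        data_key=est.data_key_,
        conc_monomeric_mM=tr.conc_monomeric_mM,
        source=dict(tr.source),
    )


def fit_two_phase(tr: Transient) -> TransientFit:
    """Fit the two-phase model; falls back to one-phase if it cannot converge."""
    try:
        est = TwoPhaseAssociation().fit(tr.time, tr.response)
    except FitConvergenceError:
        out = fit_one_phase(tr)
        out.fallback = True
        return out
    return TransientFit(
        model="two_phase",
        k_fast=est.k_fast_,
        k_slow=est.k_slow_,
        a_fast=est.a_fast_,
        a_slow=est.a_slow_,
        plateau=est.a_fast_ + est.a_slow_,
        r_squared=est.r_squared_,
        residuals=est.residuals_,
        n_points=tr.time.size,
        n_iter=est.n_iter_,
        data_key=est.data_key_,
        degenerate=est.degenerate_,
        conc_monomeric_mM=tr.conc_monomeric_mM,
        source=dict(tr.source),
    )


def _aicc(n: int, ss_res: float, k: int) -> float:
    """Small-sample-corrected Akaike information criterion (least-squares form)."""
    ss = max(ss_res, 1e-300)
    return n * np.log(ss / n) + 2 * k + 2 * k * (k + 1) / max(n - k - 1, 1)


def residual_runs_z(residuals: Sequence[float]) -> float:
    """Wald-Wolfowitz runs statistic on residual signs.

    Strongly negative z means fewer sign runs than expected under
    independence, i.e. systematic residual asymmetry (lack of fit).
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0])
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    return (runs - mu) / np.sqrt(var) if var > 0 else 0.0


@dataclass(frozen=True)
class ModelComparison:
    """Head-to-head comparison of two fits of the same transient."""

    delta_r_squared: float  # r2(fit2) - r2(fit1)
    delta_aicc: float  # aicc(fit2) - aicc(fit1); negative favours fit2
    preferred: str  # "fit1" | "fit2"
    runs_z_fit1: float
    runs_z_fit2: float


def compare_models(fit1: TransientFit, fit2: TransientFit) -> ModelComparison:
    """Compare two fits of the same transient (ΔR², ΔAICc, residual runs)."""
    if fit1.data_key != fit2.data_key:
        raise DomainError("fits are not on the same transient")
    n = fit1.n_points
    a1 = _aicc(n, float(np.sum(fit1.residuals**2)), fit1.n_parameters)
    a2 = _aicc(n, float(np.sum(fit2.residuals**2)), fit2.n_parameters)
    return ModelComparison(
        delta_r_squared=fit2.r_squared - fit1.r_squared,
        delta_aicc=a2 - a1,
        preferred="fit2" if a2 < a1 else "fit1",
        runs_z_fit1=residual_runs_z(fit1.residuals),
        runs_z_fit2=residual_runs_z(fit2.residuals),
    )


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean ± SEM of k_obs over replicate injections."""

    mean_k_obs: float
    sem_k_obs: Optional[float]  # None when n = 1 (SEM undefined)
    n: int


def aggregate_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Mean and SEM (sample SD / sqrt(n)) of replicate k_obs values."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise DomainError("no replicate values supplied")
    if v.size == 1:
        return ReplicateSummary(mean_k_obs=float(v[0]), sem_k_obs=None, n=1)
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
    return ReplicateSummary(mean_k_obs=float(v.mean()), sem_k_obs=sem, n=int(v.size))
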