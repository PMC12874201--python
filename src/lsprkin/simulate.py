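"""Synthetic dual-channel sensorgram generator with known ground truth.

Emulates the standard flow-injection protocol: a pre-injection baseline
hold, a 300 s association phase while analyte flows at constant
concentration, then a 300 s buffer-wash dissociation phase, sampled at 1 Hz.
The active channel carries baseline + bulk refractive-index pulse + binding
+ Gaussian noise; the reference channel carries the same baseline and bulk
pulse (no binding) with independent noise, so reference subtraction cancels
the pulse exactly in expectation.

Ground-truth kinetics use the closed-form pseudo-first-order model from
:mod:`lsprkin.model`; a two-compartment, quasi-steady-state
transport-limited variant is provided for robustness testing and converges
to the closed form as the transport coefficient grows.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so any config is bit-reproducible.

Defaults mirror the study conditions: truth k_on = 0.03705 per uM per s,
k_off = 0.0143 per s, the five-step monomeric gradient 1, 0.5, 0.25, 0.125,
0.0625 mM, duplicate injections, PEI repeat unit 43.07 g/mol with chain mass
25,000 g/mol.  R_max = 1000 RU and noise_sd = 2 RU are placeholders: the
instrument's true amplitude scale and noise floor are not published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import DomainError
from .model import (
    KineticParams,
    PolymerSpec,
    Sensorgram,
    association_response,
    dissociation_response,
    observed_rate,
)
from .molweight import monomeric_to_polymeric

DEFAULT_POLYMER = PolymerSpec("PEI", repeat_unit_mass=43.07, chain_mass=25000.0)
DEFAULT_PARAMS = KineticParams(k_on=0.03705, k_off=0.0143)
DEFAULT_GRADIENT_MM = (1.0, 0.5, 0.25, 0.125, 0.0625)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and protocol for synthetic sensorgrams.

    Durations in seconds, sample_rate in Hz, RU quantities in RU,
    concentrations monomeric mM.  ``baseline_duration`` is the pre-injection
    hold used downstream for baseline zeroing.
    """

    params: KineticParams = DEFAULT_PARAMS
    r_max: float = 1000.0
    concentrations_mM: Sequence[float] = DEFAULT_GRADIENT_MM
    polymer: PolymerSpec = DEFAULT_POLYMER
    noise_sd: float = 2.0
    bulk_shift: float = 25.0
    baseline: float = 0.0
    sample_rate: float = 1.0
    baseline_duration: float = 30.0
    association_duration: float = 300.0
    dissociation_duration: float = 300.0
    replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if not self.sample_rate > 0:
            raise DomainError("sample_rate must be > 0")
        for nm in ("association_duration", "dissociation_duration"):
            if not getattr(self, nm) > 0:
                raise DomainError(f"{nm} must be > 0")
        if self.baseline_duration < 0:
            raise DomainError("baseline_duration must be >= 0")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")


def _time_grid(cfg: SimulationConfig) -> np.ndarray:
    total = cfg.baseline_duration + cfg.association_duration + cfg.dissociation_duration
    n = int(round(total * cfg.sample_rate)) + 1
    return np.arange(n) / cfg.sample_rate


def _noiseless_binding(cfg: SimulationConfig, conc_mM: float, t: np.ndarray) -> np.ndarray:
    """Binding component on the full grid (zero before injection)."""
    t0 = cfg.baseline_duration
    t1 = t0 + cfg.association_duration
    conc_uM = monomeric_to_polymeric(conc_mM, cfg.polymer)
    out = np.zeros_like(t)
    assoc = (t >= t0) & (t <= t1)
    out[assoc] = association_response(t[assoc] - t0, conc_uM, cfg.params, cfg.r_max)
    r_end = association_response(cfg.association_duration, conc_uM, cfg.params, cfg.r_max)
    dissoc = t > t1
    out[dissoc] = dissociation_response(t[dissoc] - t1, r_end, cfg.params.k_off)
    return out


def simulate_sensorgram(
    cfg: SimulationConfig,
    conc_mM: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Sensorgram:
    """One dual-channel sensorgram at the given (or first configured) concentration.

    Deterministic given the config seed; pass ``rng`` to draw noise from an
    externally managed stream (used by :func:`simulate_gradient`).
    """
    if conc_mM is None:
        conc_mM = cfg.concentrations_mM[0]
    if conc_mM < 0:
        raise DomainError("concentration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = _time_grid(cfg)
    t0 = cfg.baseline_duration
    t1 = t0 + cfg.association_duration
    pulse = np.where((t >= t0) & (t <= t1), cfg.bulk_shift, 0.0)
    binding = _noiseless_binding(cfg, conc_mM, t)
    active = cfg.baseline + pulse + binding + rng.normal(0.0, cfg.noise_sd, t.size)
    reference = cfg.baseline + pulse + rng.normal(0.0, cfg.noise_sd, t.size)
    return Sensorgram(
        time=t,
        response_active=active,
        response_reference=reference,
        injection_start=t0,
        injection_end=t1,
        analyte=cfg.polymer,
        monomeric_concentration_mM=conc_mM,
        metadata={"seed": cfg.seed, "truth_k_on": cfg.params.k_on,
                  "truth_k_off": cfg.params.k_off, "truth_r_max": cfg.r_max},
    )


def simulate_gradient(cfg: SimulationConfig) -> list[Sensorgram]:
    """One sensorgram per concentration per replicate, seeded deterministically.

    Child seeds are spawned from ``cfg.seed`` via ``SeedSequence``, so the
    full gradient is reproducible and individual traces are independent.
    """
    if len(cfg.concentrations_mM) < 3:
        raise DomainError("gradient needs >= 3 concentrations")
    n = len(cfg.concentrations_mM) * cfg.replicates
    children = np.random.SeedSequence(cfg.seed).spawn(n)
    out = []
    i = 0
    for conc in cfg.concentrations_mM:
        for rep in range(cfg.replicates):
            s = simulate_sensorgram(cfg, conc, rng=np.random.default_rng(children[i]))
            s.metadata["replicate"] = rep
            out.append(s)
            i += 1
    return out


def simulate_multilayer(
    n_bilayers: int, delta_ru: float = 500.0, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise layer-by-layer buildup: cumulative RU after each bilayer.

    Returns (bilayer index 1..n, RU) with RU_i = i*delta_ru + Gaussian noise.
    """
    if n_bilayers < 1:
        raise DomainError("n_bilayers must be >= 1")
    rng = np.random.default_rng(seed)
    idx = np.arange(1, n_bilayers + 1, dtype=float)
    ru = idx * delta_ru + rng.normal(0.0, noise_sd, n_bilayers)
    return idx, ru


def simulate_transport_limited(
    cfg: SimulationConfig, k_m: float, conc_mM: Optional[float] = None
) -> Sensorgram:
    """Noiseless sensorgram under two-compartment mass-transport limitation.

    The surface concentration C_s follows the quasi-steady-state balance
    k_m*(C_bulk - C_s) = k_on*C_s*(R_max - R) - k_off*R, giving

        dR/dt = k_on*C_s*(R_max - R) - k_off*R,
        C_s   = (k_m*C_bulk + k_off*R) / (k_m + k_on*(R_max - R)).

    ``k_m`` is in RU per uM per second; as k_m -> inf, C_s -> C_bulk and the
    curve converges to the reaction-limited closed form.  Single channel,
    no noise — this variant exists for robustness testing.
    """
    if not k_m > 0:
        raise DomainError("k_m must be positive")
    if conc_mM is None:
        conc_mM = cfg.concentrations_mM[0]
    conc_uM = monomeric_to_polymeric(conc_mM, cfg.polymer)
    k_on, k_off, r_max = cfg.params.k_on, cfg.params.k_off, cfg.r_max
    t = _time_grid(cfg)
    t0 = cfg.baseline_duration
    t1 = t0 + cfg.association_duration

    def rhs(_t, r, c_bulk):
        c_s = (k_m * c_bulk + k_off * r[0]) / (k_m + k_on * (r_max - r[0]))
        return [k_on * c_s * (r_max - r[0]) - k_off * r[0]]

    out = np.zeros_like(t)
    assoc = (t >= t0) & (t <= t1)
    sol = solve_ivp(rhs, (0.0, cfg.association_duration), [0.0], args=(conc_uM,),
                    t_eval=t[assoc] - t0, method="LSODA", rtol=1e-9, atol=1e-9)
    if not sol.success:
        raise DomainError(f"transport integrator failed: {sol.message}")
    out[assoc] = sol.y[0]
    r_end = float(sol.y[0, -1])
    dissoc = t > t1
    if np.any(dissoc):
        sol2 = solve_ivp(rhs, (0.0, cfg.dissociation_duration), [r_end], args=(0.0,),
                         t_eval=t[dissoc] - t1, method="LSODA", rtol=1e-9, atol=1e-9)
        if not sol2.success:
            raise DomainError(f"transport integrator failed: {sol2.message}")
        out[dissoc] = sol2.y[0]
    return Sensorgram(
        time=t,
        response_active=cfg.baseline + out,
        injection_start=t0,
        injection_end=t1,
        analyte=cfg.polymer,
        monomeric_concentration_mM=conc_mM,
        metadata={"k_m": k_m, "transport_limited": True},
    )
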