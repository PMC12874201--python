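import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lsprkin as lk
from lsprkin import datasets as ds
from lsprkin.model import KineticParams, PolymerSpec
from lsprkin.simulate import SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pei() -> PolymerSpec:
    return ds.PEI


@pytest.fixture(scope="session")
def pazo() -> PolymerSpec:
    return ds.PAZO


@pytest.fixture(scope="session")
def pei_table():
    """(monomeric conc mM, k_obs 1/s) for the known-M_n orientation."""
    return [(c, k) for c, k, *_ in ds.PEI_KOBS]


@pytest.fixture(scope="session")
def pazo_table():
    """(monomeric conc mM, k_obs 1/s) for the unknown-M_n orientation."""
    return [(c, k) for c, k, *_ in ds.PAZO_KOBS]


@pytest.fixture(scope="session")
def truth() -> KineticParams:
    return KineticParams(k_on=0.037, k_off=0.014)


@pytest.fixture(scope="session")
def pazo_true() -> PolymerSpec:
    """Unknown polymer with its ground-truth chain mass (DP exactly 642)."""
    return PolymerSpec("PAZO", repeat_unit_mass=401.0, chain_mass=401.0 * 642)


@pytest.fixture
def noiseless_cfg(truth) -> SimulationConfig:
    return SimulationConfig(params=truth, noise_sd=0.0, bulk_shift=0.0,
                            replicates=1, seed=0)


@pytest.fixture
def one_phase_transient():
    """Noiseless single-exponential transient: k_obs = 0.05 1/s, C = 800 RU."""
    t = np.arange(301, dtype=float)
    return lk.Transient(time=t, response=800.0 * -np.expm1(-0.05 * t))
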