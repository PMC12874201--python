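"""Simulator: determinism, ground-truth fidelity, transport-limited variant."""

import numpy as np
import pytest

import lsprkin as lk
from lsprkin import (
    DomainError,
    KineticParams,
    SimulationConfig,
    linearity_check,
    simulate_gradient,
    simulate_multilayer,
    simulate_sensorgram,
    simulate_transport_limited,
)
from lsprkin.model import association_response, equilibrium_response, observed_rate
from lsprkin.molweight import monomeric_to_polymeric
from lsprkin.preprocess import prepare


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=42)
        a = simulate_sensorgram(cfg, 1.0)
        b = simulate_sensorgram(cfg, 1.0)
        assert np.array_equal(a.response_active, b.response_active)
        assert np.array_equal(a.response_reference, b.response_reference)

    def test_gradient_reproducible_and_traces_independent(self):
        cfg = SimulationConfig(seed=7)
        g1, g2 = simulate_gradient(cfg), simulate_gradient(cfg)
        for a, b in zip(g1, g2):
            assert np.array_equal(a.response_active, b.response_active)
        assert not np.array_equal(g1[0].response_active, g1[1].response_active)


class TestGroundTruth:
    def test_noiseless_equals_closed_form(self, truth):
        cfg = SimulationConfig(params=truth, noise_sd=0.0, bulk_shift=0.0,
                               baseline=0.0, seed=0)
        s = simulate_sensorgram(cfg, 1.0)
        conc = monomeric_to_polymeric(1.0, cfg.polymer)
        assoc = (s.time >= s.injection_start) & (s.time <= s.injection_end)
        expected = association_response(s.time[assoc] - s.injection_start,
                                        conc, truth, cfg.r_max)
        assert np.allclose(s.response_active[assoc], expected, atol=1e-12)

    def test_continuous_at_injection_end(self, truth):
        """Dissociation picks up exactly where association ends (no jump)."""
        cfg = SimulationConfig(params=truth, noise_sd=0.0, bulk_shift=0.0, seed=0)
        s = simulate_sensorgram(cfg, 1.0)
        i_end = int(np.searchsorted(s.time, s.injection_end))
        r_end = s.response_active[i_end]
        dt = s.time[i_end + 1] - s.time[i_end]
        from lsprkin.model import dissociation_response
        assert s.response_active[i_end + 1] == pytest.approx(
            dissociation_response(dt, r_end, truth.k_off), rel=1e-9)

    def test_gradient_cardinality(self):
        cfg = SimulationConfig(replicates=2)
        assert len(simulate_gradient(cfg)) == 10

    def test_noiseless_gradient_yields_exact_rate_line(self, truth):
        """Fitted k_obs vs chain concentration is exactly affine: slope k_on."""
        cfg = SimulationConfig(params=truth, noise_sd=0.0, bulk_shift=0.0,
                               replicates=1, seed=0)
        concs, kobs = [], []
        for s in simulate_gradient(cfg):
            fit = lk.fit_one_phase(prepare(s))
            concs.append(monomeric_to_polymeric(s.monomeric_concentration_mM, cfg.polymer))
            kobs.append(fit.k_obs)
        line = lk.fit_rate_line(concs, kobs)
        assert line.slope == pytest.approx(truth.k_on, rel=1e-6)
        assert line.intercept == pytest.approx(truth.k_off, rel=1e-6)

    def test_reference_channel_cancels_bulk_pulse(self):
        """No-binding injection: after correction the in-window mean is ~0."""
        cfg = SimulationConfig(noise_sd=2.0, bulk_shift=50.0, seed=3)
        s = simulate_sensorgram(cfg, 0.0)  # zero concentration, no binding
        corrected = lk.subtract_reference(s)
        win = (s.time >= s.injection_start) & (s.time <= s.injection_end)
        sem = np.sqrt(2) * cfg.noise_sd / np.sqrt(win.sum())
        assert abs(corrected.response_active[win].mean()) < 4 * sem

    def test_noise_sd_scales_fit_uncertainty(self, truth):
        """Fitted k_obs spread across seeds grows with the noise level."""
        spreads = []
        for sd in (0.5, 2.0, 8.0):
            ks = []
            for seed in range(50):
                cfg = SimulationConfig(params=truth, noise_sd=sd, bulk_shift=0.0,
                                       replicates=1, seed=seed)
                ks.append(lk.fit_one_phase(prepare(simulate_sensorgram(cfg, 1.0))).k_obs)
            spreads.append(np.std(ks))
        assert spreads[0] < spreads[1] < spreads[2]


class TestMultilayer:
    def test_noiseless_buildup(self):
        idx, ru = simulate_multilayer(5, delta_ru=500.0)
        assert np.array_equal(ru, [500.0, 1000.0, 1500.0, 2000.0, 2500.0])
        assert linearity_check(idx, ru).r_squared == pytest.approx(1.0)

    def test_noisy_buildup_stays_linear(self):
        idx, ru = simulate_multilayer(5, delta_ru=500.0, noise_sd=10.0, seed=0)
        assert linearity_check(idx, ru).r_squared > 0.99

    def test_requires_at_least_one_bilayer(self):
        with pytest.raises(DomainError):
            simulate_multilayer(0)


class TestTransportLimited:
    def test_converges_to_reaction_limited(self, truth):
        cfg = SimulationConfig(params=truth, noise_sd=0.0, bulk_shift=0.0, seed=0)
        k_m = 1e6 * truth.k_on * cfg.r_max
        fast = simulate_transport_limited(cfg, k_m, 1.0)
        reaction = simulate_sensorgram(cfg, 1.0)
        conc = monomeric_to_polymeric(1.0, cfg.polymer)
        req = equilibrium_response(conc, truth, cfg.r_max)
        dev = np.max(np.abs(fast.response_active - reaction.response_active))
        assert dev < 1e-3 * req

    def test_small_k_m_slows_initial_rise(self, truth):
        cfg = SimulationConfig(params=truth, noise_sd=0.0, bulk_shift=0.0, seed=0)
        slow = simulate_transport_limited(cfg, 0.01 * truth.k_on * cfg.r_max, 1.0)
        reaction = simulate_sensorgram(cfg, 1.0)
        t0 = cfg.baseline_duration
        early = (slow.time > t0) & (slow.time <= t0 + 30)
        assert np.all(slow.response_active[early] < reaction.response_active[early])

    def test_flow_rate_emulation_changes_shape(self, truth):
        """Two finite k_m values give quantifiably different association fronts."""
        cfg = SimulationConfig(params=truth, noise_sd=0.0, bulk_shift=0.0, seed=0)
        lo = simulate_transport_limited(cfg, 0.05 * truth.k_on * cfg.r_max, 1.0)
        hi = simulate_transport_limited(cfg, 0.2 * truth.k_on * cfg.r_max, 1.0)
        t0 = cfg.baseline_duration
        early = (lo.time > t0) & (lo.time <= t0 + 40)
        gap = np.max(hi.response_active[early] - lo.response_active[early])
        assert gap > 0  # faster transport -> steeper early front

    def test_invalid_k_m(self, truth):
        cfg = SimulationConfig(params=truth)
        with pytest.raises(DomainError):
            simulate_transport_limited(cfg, 0.0, 1.0)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"noise_sd": -1.0}, {"sample_rate": 0.0}, {"replicates": 0},
        {"association_duration": 0.0},
    ])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(DomainError):
            SimulationConfig(**kwargs)

    def test_gradient_needs_three_concentrations(self):
        cfg = SimulationConfig(concentrations_mM=(1.0, 0.5))
        with pytest.raises(DomainError):
            simulate_gradient(cfg)


def test_pipeline_consistency_with_model_arithmetic():
    """Simulated k_obs at 1 mM matches observed_rate at the converted chain conc."""
    params = KineticParams(k_on=0.03705, k_off=0.0143)
    cfg = SimulationConfig(params=params, noise_sd=0.0, bulk_shift=0.0, seed=0)
    s = simulate_sensorgram(cfg, 1.0)
    fit = lk.fit_one_phase(prepare(s))
    conc = monomeric_to_polymeric(1.0, cfg.polymer)  # ~1.723 uM
    assert fit.k_obs == pytest.approx(observed_rate(conc, params), rel=1e-6)
    assert fit.k_obs == pytest.approx(0.078, abs=5e-4)
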