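"""Exponential transient fitting: recovery, equivariance, model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from lsprkin import (
    DegenerateDataError,
    DomainError,
    OnePhaseAssociation,
    Transient,
    TwoPhaseAssociation,
    aggregate_replicates,
    compare_models,
    fit_one_phase,
    fit_two_phase,
)


def one_phase_data(k, c, n=301, dt=1.0, noise_sd=0.0, seed=0, offset=0.0):
    t = np.arange(n) * dt
    y = c * -np.expm1(-k * t) + offset
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, n)
    return t, y


class TestOnePhase:
    def test_noiseless_recovery(self):
        t, y = one_phase_data(0.05, 800.0)
        fit = fit_one_phase(Transient(time=t, response=y))
        assert fit.k_obs == pytest.approx(0.05, rel=1e-6)
        assert fit.plateau == pytest.approx(800.0, rel=1e-6)
        assert fit.r_squared > 1 - 1e-10

    def test_constant_signal_is_degenerate(self):
        t = np.arange(301, dtype=float)
        with pytest.raises(DegenerateDataError):
            fit_one_phase(Transient(time=t, response=np.zeros(301)))

    def test_noisy_recovery_within_3_se(self):
        t, y = one_phase_data(0.075, 800.0, noise_sd=2.0, seed=0)
        fit = fit_one_phase(Transient(time=t, response=y))
        assert abs(fit.k_obs - 0.075) < 3 * fit.se_k_obs
        assert fit.se_k_obs > 0

    def test_free_offset_recovers_shift(self):
        t, y = one_phase_data(0.05, 800.0, offset=25.0)
        est = OnePhaseAssociation(free_offset=True).fit(t, y)
        assert est.offset_ == pytest.approx(25.0, abs=1e-4)
        assert est.k_obs_ == pytest.approx(0.05, rel=1e-5)

    @given(s=st.floats(0.1, 100))
    def test_scale_equivariance(self, s):
        t, y = one_phase_data(0.04, 500.0, n=121)
        a = OnePhaseAssociation().fit(t, y)
        b = OnePhaseAssociation().fit(t, s * y)
        assert b.plateau_ == pytest.approx(s * a.plateau_, rel=1e-6)
        assert b.k_obs_ == pytest.approx(a.k_obs_, rel=1e-6)

    @given(s=st.floats(0.5, 20))
    def test_time_unit_equivariance(self, s):
        t, y = one_phase_data(0.4, 500.0, n=121, dt=0.25)
        a = OnePhaseAssociation().fit(t, y)
        b = OnePhaseAssociation().fit(s * t, y)
        assert b.k_obs_ == pytest.approx(a.k_obs_ / s, rel=1e-6)

    def test_predict_round_trip_and_column_input(self):
        t, y = one_phase_data(0.05, 800.0)
        est = OnePhaseAssociation().fit(t.reshape(-1, 1), y)
        assert np.allclose(est.predict(t), y, atol=1e-6)

    def test_sklearn_protocol(self):
        est = OnePhaseAssociation(free_offset=True)
        assert clone(est).get_params()["free_offset"] is True
        est.set_params(free_offset=False)
        assert est.get_params()["free_offset"] is False


class TestTwoPhase:
    def test_biphasic_noiseless_recovery(self):
        t = np.arange(601, dtype=float)
        y = 400.0 * -np.expm1(-0.1 * t) + 400.0 * -np.expm1(-0.01 * t)
        fit = fit_two_phase(Transient(time=t, response=y))
        assert fit.k_fast == pytest.approx(0.1, rel=1e-4)
        assert fit.k_slow == pytest.approx(0.01, rel=1e-4)
        assert fit.a_fast == pytest.approx(400.0, rel=1e-3)
        assert not fit.degenerate

    def test_single_exponential_truth_flags_degenerate(self):
        t, y = one_phase_data(0.05, 800.0)
        fit = fit_two_phase(Transient(time=t, response=y))
        assert fit.degenerate  # rates collapse or one amplitude vanishes

    def test_minimum_sample_count(self):
        t = np.arange(6, dtype=float)
        with pytest.raises(DomainError):
            TwoPhaseAssociation().fit(t, np.exp(-t))

    def test_canonical_ordering(self):
        t = np.arange(601, dtype=float)
        y = 100.0 * -np.expm1(-0.2 * t) + 700.0 * -np.expm1(-0.005 * t)
        fit = fit_two_phase(Transient(time=t, response=y))
        assert fit.k_fast >= fit.k_slow

    def test_one_phase_nested_in_two_phase(self):
        """With the slow amplitude at zero the two-phase curve is the one-phase curve."""
        t, y = one_phase_data(0.05, 800.0)
        one = OnePhaseAssociation().fit(t, y)
        two = TwoPhaseAssociation().fit(t, y)
        two.a_fast_, two.k_fast_ = one.plateau_, one.k_obs_
        two.a_slow_ = 0.0
        assert np.allclose(two.predict(t), one.predict(t))


class TestCompareModels:
    def test_identical_fits(self):
        t, y = one_phase_data(0.05, 800.0, noise_sd=2.0, seed=1)
        tr = Transient(time=t, response=y)
        f1, f2 = fit_one_phase(tr), fit_one_phase(tr)
        cmp = compare_models(f1, f2)
        assert cmp.delta_r_squared == 0.0
        assert cmp.delta_aicc == 0.0

    def test_mismatched_transients_rejected(self):
        t, y = one_phase_data(0.05, 800.0, noise_sd=2.0, seed=1)
        t2, y2 = one_phase_data(0.05, 800.0, noise_sd=2.0, seed=2)
        with pytest.raises(DomainError):
            compare_models(fit_one_phase(Transient(time=t, response=y)),
                           fit_one_phase(Transient(time=t2, response=y2)))

    @pytest.mark.parametrize("biphasic, expected", [(False, "fit1"), (True, "fit2")])
    def test_information_criterion_selects_truth(self, biphasic, expected):
        """AICc prefers the generating model in the majority of noisy replicates."""
        t = np.arange(0, 601, 2.0)
        votes = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            if biphasic:
                y = 500.0 * -np.expm1(-0.1 * t) + 500.0 * -np.expm1(-0.01 * t)
            else:
                y = 800.0 * -np.expm1(-0.05 * t)
            tr = Transient(time=t, response=y + rng.normal(0, 2.0, t.size))
            cmp = compare_models(fit_one_phase(tr), fit_two_phase(tr))
            votes += cmp.preferred == expected
        assert votes > n_seeds / 2

    def test_runs_statistic_flags_lack_of_fit(self):
        """Fitting one phase to strongly biphasic data leaves patterned residuals."""
        t = np.arange(601, dtype=float)
        y = 500.0 * -np.expm1(-0.1 * t) + 500.0 * -np.expm1(-0.005 * t)
        tr = Transient(time=t, response=y + np.random.default_rng(0).normal(0, 1, t.size))
        cmp = compare_models(fit_one_phase(tr), fit_two_phase(tr))
        assert cmp.runs_z_fit1 < -3  # far fewer sign runs than chance
        assert cmp.runs_z_fit1 < cmp.runs_z_fit2


class TestAggregateReplicates:
    def test_mean_and_sem(self):
        s = aggregate_replicates([2.0, 4.0])
        assert s.mean_k_obs == 3.0 and s.sem_k_obs == 1.0 and s.n == 2

    def test_duplicate_kobs_closed_form(self):
        s = aggregate_replicates([0.07, 0.08])
        assert s.mean_k_obs == pytest.approx(0.075)
        assert s.sem_k_obs == pytest.approx(0.005)

    def test_single_value_flags_undefined_sem(self):
        s = aggregate_replicates([0.0712])
        assert s.mean_k_obs == 0.0712 and s.sem_k_obs is None and s.n == 1

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            aggregate_replicates([])


def test_agrees_with_independent_fitter():
    """Cross-check against lmfit on a noisy transient (independent NLS route)."""
    lmfit = pytest.importorskip("lmfit")
    t, y = one_phase_data(0.06, 900.0, noise_sd=3.0, seed=4)
    ours = OnePhaseAssociation().fit(t, y)

    def f(t, c, k):
        return c * (1 - np.exp(-k * t))

    res = lmfit.Model(f).fit(y, t=t, c=max(y), k=0.02)
    assert ours.k_obs_ == pytest.approx(res.params["k"].value, rel=1e-6)
    assert ours.plateau_ == pytest.approx(res.params["c"].value, rel=1e-6)
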