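"""Closed-form module kinetics against analytic limits and a numerical oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modvelo.kinetics import (
    GeneRates,
    ModuleKinetics,
    expected_counts,
    module_alpha,
    module_components,
    module_spliced,
    module_unspliced,
    velocity,
)

from conftest import integrate_modules, random_kinetics


def single_module(ahat=2.0, lam_on=1.0, lam_off=1.0, t_on=0.0, t_off=np.inf):
    return ModuleKinetics(
        target_rate=[[ahat]],
        activation_rate=[lam_on],
        deactivation_rate=[lam_off],
        switch_on=[t_on],
        switch_off=[t_off],
    )


class TestAlpha:
    def test_zero_before_switch_on(self):
        kin = single_module(t_on=1.0)
        assert module_alpha(np.array([0.0, 0.5, 1.0]), kin).max() == 0.0

    def test_relaxation_closed_form(self):
        # alpha-hat=2, lam=1, T_on=0, t=1  ->  2 (1 - e^-1)
        kin = single_module(ahat=2.0, lam_on=1.0)
        a = module_alpha(np.array([1.0]), kin)[0, 0, 0]
        assert a == pytest.approx(2.0 * (1.0 - np.exp(-1.0)), abs=1e-12)

    def test_saturates_at_target(self):
        kin = single_module(ahat=2.0, lam_on=1.0)
        assert module_alpha(np.array([60.0]), kin)[0, 0, 0] == pytest.approx(2.0, abs=1e-9)

    def test_nonfinite_time_rejected(self):
        kin = single_module()
        with pytest.raises(ValueError, match="finite"):
            module_alpha(np.array([np.nan]), kin)


class TestSteadyStates:
    def test_perpetually_on_fixed_points(self):
        """u -> ahat/beta, s -> ahat/gamma, velocity -> 0 at long times."""
        kin = single_module(ahat=2.0, lam_on=0.8)
        rates = GeneRates(splicing=[0.5], degradation=[0.25])
        t = np.array([50.0 / 0.25])
        u = module_unspliced(t, kin, rates)[0, 0, 0]
        s = module_spliced(t, kin, rates)[0, 0, 0]
        v = velocity(t, kin, rates)[0, 0]
        assert u == pytest.approx(2.0 / 0.5, abs=1e-9)
        assert s == pytest.approx(2.0 / 0.25, abs=1e-9)
        assert abs(v) < 1e-9

    def test_step_limit_induction(self):
        """lam -> inf recovers the classical two-state induction solution."""
        kin = single_module(ahat=1.0, lam_on=2e6)
        rates = GeneRates(splicing=[1.0], degradation=[1.0])
        t = np.array([1.0])
        u = module_unspliced(t, kin, rates)[0, 0, 0]
        s = module_spliced(t, kin, rates)[0, 0, 0]
        # classical: u = 1 - e^-t ; s (repeated eigenvalue) = 1 - e^-t - t e^-t
        assert u == pytest.approx(1.0 - np.exp(-1.0), rel=1e-5)
        assert s == pytest.approx(1.0 - 2.0 * np.exp(-1.0), rel=1e-5)
        v = velocity(t, kin, rates)[0, 0]
        assert v == pytest.approx(np.exp(-1.0), rel=1e-5)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(4))
    def test_random_parameters_match_integration(self, seed):
        rng = np.random.default_rng(seed)
        kin, rates = random_kinetics(rng, n_modules=3, n_genes=3)
        times = np.linspace(0.0, 3.0 * kin.switch_off.max(), 7)
        a_n, u_n, s_n = integrate_modules(kin, rates, times)
        a, u, s = module_components(times, kin, rates)
        assert np.allclose(a, a_n, rtol=1e-6, atol=1e-9)
        assert np.allclose(u, u_n, rtol=1e-6, atol=1e-9)
        assert np.allclose(s, s_n, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("kind", ["beta_gamma", "lam_beta", "lam_gamma"])
    @pytest.mark.parametrize("gap", [0.0, 1e-6, 1e-3])
    def test_degenerate_rates_are_stable(self, kind, gap):
        """Nearly equal eigenvalues do not cause catastrophic cancellation."""
        rng = np.random.default_rng(11)
        kin, rates = random_kinetics(rng, n_modules=2, n_genes=2, degenerate=(kind, gap))
        times = np.linspace(0.05, 3.0 * kin.switch_off.max(), 9)
        _, u_n, s_n = integrate_modules(kin, rates, times)
        _, u, s = module_components(times, kin, rates)
        assert np.allclose(u, u_n, rtol=1e-6, atol=1e-9)
        assert np.allclose(s, s_n, rtol=1e-6, atol=1e-9)

    def test_repeated_eigenvalue_closed_form(self):
        # beta = gamma = 1, step-like module, t = 1: s = 1 - e^-1 - e^-1
        kin = single_module(ahat=1.0, lam_on=1e7)
        rates = GeneRates(splicing=[1.0], degradation=[1.0])
        s = module_spliced(np.array([1.0]), kin, rates)[0, 0, 0]
        assert s == pytest.approx(1.0 - 2.0 * np.exp(-1.0), rel=1e-5)


class TestContinuityAndSwitching:
    def test_continuity_at_switches(self):
        rng = np.random.default_rng(3)
        kin, rates = random_kinetics(rng, n_modules=2, n_genes=2)
        eps = 1e-9
        for t_star in np.concatenate([kin.switch_on, kin.switch_off]):
            lo = module_components(np.array([t_star - eps]), kin, rates)
            hi = module_components(np.array([t_star + eps]), kin, rates)
            for a, b in zip(lo, hi):
                assert np.all(np.abs(a - b) < 1e-6)

    def test_zero_until_switch_on(self):
        kin = single_module(t_on=2.0, t_off=5.0)
        rates = GeneRates(splicing=[0.7], degradation=[0.3])
        comp = module_components(np.array([0.0, 1.0, 2.0]), kin, rates)
        for c in comp:
            assert np.all(c == 0.0)

    def test_decay_after_switch_off(self):
        kin = single_module(ahat=2.0, lam_on=3.0, lam_off=1.5, t_on=0.0, t_off=2.0)
        rates = GeneRates(splicing=[0.8], degradation=[0.5])
        times = np.array([2.0, 4.0, 8.0, 80.0])
        s = module_spliced(times, kin, rates)[:, 0, 0]
        assert s[0] > s[-1]
        assert s[-1] == pytest.approx(0.0, abs=1e-8)


class TestSuperposition:
    def test_two_identical_modules_double_single(self):
        kin1 = single_module(ahat=1.5, lam_on=1.2, t_on=0.5, t_off=3.0)
        kin2 = ModuleKinetics(
            target_rate=np.vstack([kin1.target_rate, kin1.target_rate]),
            activation_rate=np.repeat(kin1.activation_rate, 2),
            deactivation_rate=np.repeat(kin1.deactivation_rate, 2),
            switch_on=np.repeat(kin1.switch_on, 2),
            switch_off=np.repeat(kin1.switch_off, 2),
        )
        rates = GeneRates(splicing=[0.9], degradation=[0.4])
        t = np.linspace(0, 6, 13)
        e1 = expected_counts(t, kin1, rates)
        e2 = expected_counts(t, kin2, rates)
        assert np.allclose(e2.spliced, 2.0 * e1.spliced, rtol=1e-12)
        assert np.allclose(e2.unspliced, 2.0 * e1.unspliced, rtol=1e-12)

    def test_totals_match_joint_integration(self):
        rng = np.random.default_rng(21)
        kin, rates = random_kinetics(rng, n_modules=3, n_genes=2)
        times = np.linspace(0.0, 2.5 * kin.switch_off.max(), 6)
        _, u_n, s_n = integrate_modules(kin, rates, times)
        exp = expected_counts(times, kin, rates)
        assert np.allclose(exp.unspliced, u_n.sum(axis=1), rtol=1e-6, atol=1e-9)
        assert np.allclose(exp.spliced, s_n.sum(axis=1), rtol=1e-6, atol=1e-9)
        assert np.allclose(exp.unspliced, exp.unspliced_components.sum(axis=1))

    def test_empty_module_set_rejected(self):
        with pytest.raises(ValueError):
            ModuleKinetics(
                target_rate=np.zeros((0, 2)),
                activation_rate=np.zeros(0),
                deactivation_rate=np.zeros(0),
                switch_on=np.zeros(0),
                switch_off=np.zeros(0),
            )


class TestVelocity:
    def test_finite_difference_oracle(self):
        """velocity(t) matches a central finite difference of spliced counts."""
        rng = np.random.default_rng(5)
        kin, rates = random_kinetics(rng, n_modules=3, n_genes=3)
        h = 1e-5
        t = np.linspace(0.3, 2.0 * kin.switch_off.max(), 11)
        v = velocity(t, kin, rates)
        s_hi = expected_counts(t + h, kin, rates).spliced
        s_lo = expected_counts(t - h, kin, rates).spliced
        assert np.allclose(v, (s_hi - s_lo) / (2 * h), rtol=1e-5, atol=1e-7)

    def test_step_module_velocity_value(self):
        # beta = gamma = 1, step alpha-hat = 1, t = 1: v = u - s = e^-1
        kin = single_module(ahat=1.0, lam_on=1e7)
        rates = GeneRates(splicing=[1.0], degradation=[1.0])
        v = velocity(np.array([1.0]), kin, rates)[0, 0]
        assert v == pytest.approx(np.exp(-1.0), rel=1e-5)


@settings(max_examples=25, deadline=None)
@given(
    st.floats(0.1, 3.0),
    st.floats(0.3, 4.0),
    st.floats(0.2, 2.0),
    st.floats(0.2, 2.0),
    st.floats(0.0, 8.0),
)
def test_components_are_nonnegative(ahat, lam, beta, gamma, t):
    kin = single_module(ahat=ahat, lam_on=lam, lam_off=lam, t_on=0.5, t_off=3.5)
    rates = GeneRates(splicing=[beta], degradation=[gamma])
    a, u, s = module_components(np.array([t]), kin, rates)
    assert a.min() >= -1e-12 and u.min() >= -1e-12 and s.min() >= -1e-12


def test_fused_kernel_matches_reference_closed_forms():
    """The numba inference kernel reproduces the numpy closed forms."""
    from modvelo import _fastkin

    rng = np.random.default_rng(17)
    C, M, G, P = 40, 3, 8, 2
    t = np.sort(rng.uniform(0, 12, C))
    beta = rng.uniform(0.1, 2.0, G)
    gamma = np.where(rng.random(G) < 0.3, beta, rng.uniform(0.1, 2.0, G))
    ahat = rng.uniform(0.0, 2.0, (M, G))
    lam_on = rng.uniform(0.5, 5.0, M)
    lam_off = rng.uniform(0.5, 5.0, M)
    t_on = np.sort(rng.uniform(0.0, 4.0, M))
    dt = rng.uniform(1.0, 6.0, M)
    dt[0] = np.inf  # perpetually ON module
    rep = lambda a: np.broadcast_to(a, (P,) + a.shape).copy()
    u = np.empty((P, C, M, G))
    s = np.empty((P, C, M, G))
    _fastkin.stack_components(
        rep(t), rep(beta), rep(gamma), rep(ahat), rep(lam_on), rep(lam_off),
        rep(t_on), rep(dt), u, s,
    )
    kin = ModuleKinetics(ahat, lam_on, lam_off, t_on, t_on + dt)
    rates = GeneRates(beta, gamma)
    _, u_ref, s_ref = module_components(t, kin, rates)
    assert np.allclose(u[0], u_ref, rtol=1e-6, atol=1e-12)
    assert np.allclose(s[0], s_ref, rtol=1e-6, atol=1e-12)
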