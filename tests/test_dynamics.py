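"""Time-course integration, switch timing and fluctuation statistics."""

import numpy as np
import pytest

from let7switch.dynamics import (NOT_REACHED, NoiseSpec, default_initial_state,
                                 fluctuation_stats, simulate, simulate_noisy,
                                 switch_time)
from let7switch.equilibria import phi_at_steady_state, steady_states
from let7switch.model_core import DimensionlessParams, State

ON_STATE = 1.6739986165  # largest stable psi at alpha=0.2, gamma1=2, gamma3=0


def dimless(alpha=0.2, gamma=0.1, gamma1=2.0, gamma2=1.0, gamma3=0.0,
            epsilon=0.375) -> DimensionlessParams:
    return DimensionlessParams(alpha=alpha, gamma=gamma, gamma1=gamma1,
                               gamma2=gamma2, gamma3=gamma3, epsilon=epsilon)


def off_init(p: DimensionlessParams, psi0: float = 0.05) -> State:
    return State(phi=phi_at_steady_state(psi0, p.gamma), psi=psi0)


class TestSimulate:
    def test_stable_fixed_point_stays_fixed(self):
        p = dimless(alpha=0.05, gamma3=0.5, gamma1=2.3)
        stable = [s for s in steady_states(p) if s.stability == "stable"]
        s = stable[-1]
        traj = simulate(p, State(phi=s.phi_s, psi=s.psi_s), t_end=20.0)
        assert np.max(np.abs(traj.psi - s.psi_s)) < 1e-9
        assert np.max(np.abs(traj.phi - s.phi_s)) < 1e-9

    def test_off_start_converges_to_on_state(self):
        p = dimless()
        traj = simulate(p, off_init(p), t_end=100.0)
        assert traj.psi[-1] == pytest.approx(ON_STATE, abs=1e-6)

    def test_terminal_residual_small_after_convergence(self):
        from let7switch.model_core import rhs_dimensionless
        p = dimless()
        traj = simulate(p, off_init(p), t_end=100.0)
        d = rhs_dimensionless(State(phi=traj.phi[-1], psi=traj.psi[-1]), p)
        assert max(abs(d[0]), abs(d[1])) < 1e-6

    def test_halving_dt_barely_moves_terminal_state(self):
        p = dimless()
        t1 = simulate(p, off_init(p), t_end=50.0, dt=0.01)
        t2 = simulate(p, off_init(p), t_end=50.0, dt=0.005)
        assert abs(t1.psi[-1] - t2.psi[-1]) < 1e-8

    def test_gamma_irrelevant_for_psi_when_decoupled(self):
        """With gamma3 = 0 the let-7 trajectory ignores gamma entirely."""
        ref = None
        for gamma in (0.1, 1.0, 2.0):
            p = dimless(gamma=gamma)
            traj = simulate(p, State(phi=1.0, psi=0.05), t_end=30.0)
            if ref is None:
                ref = traj.psi
            else:
                assert np.array_equal(traj.psi, ref)

    def test_bad_steps_rejected(self):
        with pytest.raises(ValueError):
            simulate(dimless(), off_init(dimless()), t_end=0.0)
        with pytest.raises(ValueError):
            simulate(dimless(), off_init(dimless()), t_end=1.0, dt=-0.1)


class TestSwitchTime:
    def test_starting_above_threshold_switches_at_zero(self):
        p = dimless()
        traj = simulate(p, State(phi=1.0, psi=1.7), t_end=5.0)
        assert switch_time(traj, 0.05, ON_STATE) == 0.0

    def test_off_state_never_switches(self):
        p = dimless(alpha=0.05, gamma1=2.3, gamma3=0.5)
        stable = [s for s in steady_states(p) if s.stability == "stable"]
        low = stable[0]
        traj = simulate(p, State(phi=low.phi_s, psi=low.psi_s), t_end=20.0)
        assert switch_time(traj, low.psi_s, 2.0) == NOT_REACHED

    def test_switch_times_scale_inversely_with_epsilon(self):
        """gamma3 = 0 decouples psi, whose equation is epsilon * f(psi):
        time to threshold scales exactly as 1/epsilon."""
        times = {}
        for eps in (0.375, 0.1):
            p = dimless(epsilon=eps)
            traj = simulate(p, off_init(p), t_end=400.0, dt=0.01)
            times[eps] = switch_time(traj, 0.05, ON_STATE)
        assert times[0.1] / times[0.375] == pytest.approx(3.75, rel=0.01)

    def test_bad_levels_rejected(self):
        p = dimless()
        traj = simulate(p, off_init(p), t_end=1.0)
        with pytest.raises(ValueError):
            switch_time(traj, 1.0, 0.5)


class TestSimulateNoisy:
    def test_zero_variance_identical_to_deterministic(self):
        p = dimless()
        init = off_init(p)
        det = simulate(p, init, t_end=10.0)
        noisy = simulate_noisy(p, init, t_end=10.0,
                               noise=NoiseSpec(mean=p.alpha, variance=0.0,
                                               seed=5))
        assert np.array_equal(det.psi, noisy.psi)
        assert np.array_equal(det.phi, noisy.phi)

    def test_same_seed_reproduces_trajectory(self):
        p = dimless()
        init = off_init(p)
        spec = NoiseSpec(mean=0.2, variance=0.05, seed=11)
        a = simulate_noisy(p, init, t_end=10.0, noise=spec)
        b = simulate_noisy(p, init, t_end=10.0, noise=spec)
        assert np.array_equal(a.psi, b.psi)
        assert np.array_equal(a.alpha_trace, b.alpha_trace)

    def test_different_seeds_differ(self):
        p = dimless()
        init = off_init(p)
        a = simulate_noisy(p, init, t_end=5.0,
                           noise=NoiseSpec(seed=1))
        b = simulate_noisy(p, init, t_end=5.0,
                           noise=NoiseSpec(seed=2))
        assert not np.array_equal(a.psi, b.psi)

    def test_clipping_keeps_stimulus_and_state_nonnegative(self):
        p = dimless()
        init = off_init(p)
        for seed in range(10):
            traj = simulate_noisy(p, init, t_end=20.0,
                                  noise=NoiseSpec(mean=0.2, variance=0.05,
                                                  seed=seed))
            assert np.min(traj.alpha_trace) >= 0.0
            assert np.min(traj.psi) >= 0.0
            assert np.min(traj.phi) >= 0.0

    def test_stationary_mean_near_deterministic_on_state(self):
        """Fluctuating stimulus with mean 0.2 keeps let-7 at the
        deterministic on state, averaged over replicates.  Clipping is off
        here so the realized stimulus mean is exactly 0.2 (clipping shifts
        it up to E[max(N, 0)] and with it the operating point)."""
        p = dimless()
        init = off_init(p)
        means = []
        for seed in range(50):
            traj = simulate_noisy(p, init, t_end=100.0,
                                  noise=NoiseSpec(mean=0.2, variance=0.05,
                                                  clip_at_zero=False,
                                                  seed=seed))
            means.append(fluctuation_stats(traj, burn_in=70.0).mean)
        grand = float(np.mean(means))
        se = float(np.std(means, ddof=1) / np.sqrt(len(means)))
        assert abs(grand - ON_STATE) < 3.0 * se


class TestFluctuationStats:
    def test_noiseless_converged_variance_vanishes(self):
        p = dimless()
        traj = simulate(p, off_init(p), t_end=160.0)
        stats = fluctuation_stats(traj, burn_in=140.0)
        assert stats.variance < 1e-12

    def test_larger_epsilon_fluctuates_more(self):
        """The faster let-7 turns over relative to Lin28, the more stimulus
        noise propagates into its level."""
        variances = {}
        for eps in (0.1, 0.375):
            p = dimless(epsilon=eps)
            vs = []
            for seed in range(20):
                traj = simulate_noisy(p, State(phi=1.0, psi=ON_STATE),
                                      t_end=40.0,
                                      noise=NoiseSpec(mean=0.2, variance=0.05,
                                                      seed=seed))
                vs.append(fluctuation_stats(traj, burn_in=20.0).variance)
            variances[eps] = float(np.mean(vs))
        assert variances[0.375] > variances[0.1]

    def test_burn_in_past_end_rejected(self):
        p = dimless()
        traj = simulate(p, off_init(p), t_end=5.0)
        with pytest.raises(ValueError):
            fluctuation_stats(traj, burn_in=5.0)


class TestDefaultInitialState:
    def test_prefers_off_branch_state(self):
        p = dimless(alpha=0.05, gamma1=2.3, gamma3=0.5)
        init = default_initial_state(p)
        stable = [s for s in steady_states(p) if s.stability == "stable"]
        assert init.psi == pytest.approx(min(s.psi_s for s in stable))

    def test_falls_back_to_low_psi_on_nullcline(self):
        # monostable-on regime: no off-branch state exists at this alpha
        p = dimless(alpha=0.2)
        init = default_initial_state(p)
        assert init.psi == pytest.approx(0.05)
        assert init.phi == pytest.approx(phi_at_steady_state(0.05, p.gamma))
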