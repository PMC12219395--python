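"""Microscopic simulator: rates, events, dynamics, and trajectory laws."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from antcargo import ModelParams, PulseSpec
from antcargo.microsim import (
    SimState,
    build_rate_table,
    classify_outcome,
    decode_channel,
    draw_next_event,
    execute_event,
    local_force,
    role_switch_rates,
    run_trial,
    site_angles,
    step_dynamics,
    total_ant_force,
)


def small_params(**kw):
    base = dict(N_max=8, attach_boost=1.0)
    base.update(kw)
    return ModelParams(**base)


class TestRoleSwitchRates:
    def test_zero_projection_gives_basal_rates(self, default_params):
        r_pl, r_lp = role_switch_rates(np.array([0.0, 0.0]), np.array([1.0, 0.0]),
                                       default_params)
        assert r_pl == r_lp == default_params.k_c

    def test_unit_exponent(self, default_params):
        f = np.array([default_params.F_ind, 0.0])
        r_pl, r_lp = role_switch_rates(f, np.array([1.0, 0.0]), default_params)
        assert r_pl == pytest.approx(default_params.k_c / math.e)
        assert r_lp == pytest.approx(default_params.k_c * math.e)

    @given(
        fx=st.floats(-200, 200), fy=st.floats(-200, 200),
        ang=st.floats(0, 2 * math.pi),
    )
    def test_product_identity(self, fx, fy, ang):
        """Detailed structure: r_(p->l) * r_(l->p) = k_c**2 for any force."""
        p = ModelParams()
        r_pl, r_lp = role_switch_rates(
            np.array([fx, fy]), np.array([math.cos(ang), math.sin(ang)]), p
        )
        assert r_pl * r_lp == pytest.approx(p.k_c**2, rel=1e-12)
        assert r_pl > 0 and r_lp > 0

    def test_non_finite_force_rejected(self, default_params):
        with pytest.raises(ValueError):
            role_switch_rates(np.array([np.nan, 0.0]), np.array([1.0, 0.0]),
                              default_params)


class TestRateTable:
    def test_empty_cargo_only_attachment(self):
        p = small_params()
        t = build_rate_table(SimState.empty(p), p)
        assert t.R_total == pytest.approx(p.k_on * p.N_max)
        assert t.channel_rate("attach") == pytest.approx(p.k_on * p.N_max)
        assert t.channel_rate("detach") == 0.0

    def test_full_cargo_no_attachment(self):
        p = small_params()
        s = SimState.empty(p)
        s.occupied[:] = 1
        s.puller[:] = 1
        t = build_rate_table(s, p)
        assert t.channel_rate("attach") == 0.0
        assert t.channel_rate("detach") == pytest.approx(p.k_off * p.N_max)

    def test_single_uninformed_puller_at_zero_force(self):
        """With no force the per-ant rates printed in the model definition
        add up: k_off + k_ori + k_c (forget contributes only if informed)."""
        p = small_params(k_on=0.0)
        s = SimState.empty(p)
        s.occupied[0] = 1
        s.puller[0] = 1
        t = build_rate_table(s, p)
        assert t.R_total == pytest.approx(p.k_off + p.k_ori + p.k_c)

    def test_matches_engine_rate_total(self):
        """The API-level rate table agrees with the compiled engine's."""
        from antcargo._engine import _floc, _forces, _rates

        p = ModelParams(N_max=12, attach_boost=1.0)
        rng = np.random.default_rng(5)
        s = SimState.empty(p)
        s.occupied[:] = rng.integers(0, 2, p.N_max).astype(np.int8)
        s.puller[:] = s.occupied * rng.integers(0, 2, p.N_max).astype(np.int8)
        s.informed[:] = s.puller * rng.integers(0, 2, p.N_max).astype(np.int8)
        s.phi[:] = rng.uniform(-p.phi_max, p.phi_max, p.N_max)
        s.theta = 0.7
        s.F_ext_now = -4.0
        table = build_rate_table(s, p)

        alpha = site_angles(p.N_max)
        phi = s.phi.copy()
        Fx, Fy, Ftan = _forces(s.theta, s.occupied, s.puller, s.informed, phi,
                               alpha, p.f0, p.phi_max, p.nest_angle)
        flx, fly = _floc(Fx, Fy, Ftan, s.F_ext_now, s.theta, False)
        rates = np.zeros(1 + 4 * p.N_max)
        R, n_empty = _rates(s.occupied, s.puller, s.informed, phi, alpha,
                            s.theta, flx, fly, p.k_on_eff, p.k_off, p.k_forget,
                            p.k_c, p.k_ori, p.F_ind, rates)
        assert table.R_total == pytest.approx(R, rel=1e-12)
        np.testing.assert_allclose(table.rates, rates, rtol=1e-12)


class TestDrawNextEvent:
    def test_absorbing_when_no_rates(self, rng):
        p = small_params(k_on=0.0)
        t = build_rate_table(SimState.empty(p), p)
        wait, ch = draw_next_event(t, np.random.RandomState(0))
        assert wait == np.inf and ch == -1

    def test_waiting_time_is_exponential(self):
        """10^5 waits at R_total = 2 have mean 0.5 and pass a KS test."""
        from antcargo.microsim import RateTable

        table = RateTable(rates=np.array([2.0]), R_total=2.0, n_empty=1)
        rs = np.random.RandomState(42)
        waits = np.array([draw_next_event(table, rs)[0] for _ in range(100_000)])
        assert waits.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(waits)))
        ks = stats.kstest(waits, "expon", args=(0, 0.5))
        assert ks.pvalue > 1e-3

    def test_channel_frequencies_match_rates(self):
        from antcargo.microsim import RateTable

        rates = np.array([1.0, 3.0, 0.0, 6.0])
        table = RateTable(rates=rates, R_total=rates.sum(), n_empty=1)
        rs = np.random.RandomState(7)
        counts = np.zeros(4)
        n = 100_000
        for _ in range(n):
            _, ch = draw_next_event(table, rs)
            counts[ch] += 1
        expected = rates / rates.sum() * n
        chi2 = stats.chisquare(counts[rates > 0], expected[rates > 0])
        assert chi2.pvalue > 1e-3
        assert counts[2] == 0


class TestExecuteEvent:
    def test_attach_creates_informed_puller(self):
        p = small_params()
        s = SimState.empty(p)
        execute_event(s, 0, np.random.RandomState(0), p)
        assert s.N_attached == 1 and s.G == 1
        i = int(np.nonzero(s.occupied)[0][0])
        assert s.puller[i] == 1
        assert abs(s.phi[i]) <= p.phi_max + 1e-12

    def test_attach_on_full_cargo_is_logic_error(self):
        p = small_params()
        s = SimState.empty(p)
        s.occupied[:] = 1
        with pytest.raises(ValueError):
            execute_event(s, 0, np.random.RandomState(0), p)

    def test_forget_clears_flag_keeps_role(self):
        p = small_params()
        s = SimState.empty(p)
        execute_event(s, 0, np.random.RandomState(0), p)
        i = int(np.nonzero(s.occupied)[0][0])
        execute_event(s, 1 + 4 * i + 1, np.random.RandomState(1), p)
        assert s.G == 0 and s.puller[i] == 1 and s.N_attached == 1

    def test_role_switch_removes_force(self):
        p = small_params()
        s = SimState.empty(p)
        execute_event(s, 0, np.random.RandomState(0), p)
        i = int(np.nonzero(s.occupied)[0][0])
        assert np.linalg.norm(total_ant_force(s, p)) == pytest.approx(p.f0)
        execute_event(s, 1 + 4 * i + 3, np.random.RandomState(1), p)  # -> lifter
        assert np.linalg.norm(total_ant_force(s, p)) == 0.0

    def test_detach_on_empty_site_is_logic_error(self):
        p = small_params()
        s = SimState.empty(p)
        with pytest.raises(ValueError):
            execute_event(s, 1, np.random.RandomState(0), p)  # detach site 0

    def test_decode_channel(self):
        assert decode_channel(0) == ("attach", None)
        assert decode_channel(1) == ("detach", 0)
        assert decode_channel(4) == ("role_switch", 0)
        assert decode_channel(5) == ("detach", 1)


class TestForcesAndDynamics:
    def test_no_pullers_zero_force(self):
        p = small_params()
        assert np.allclose(total_ant_force(SimState.empty(p), p), 0.0)

    def test_single_aligned_puller_magnitude_f0(self):
        p = small_params()
        s = SimState.empty(p)
        s.occupied[0] = 1
        s.puller[0] = 1
        s.phi[0] = 0.0
        F = total_ant_force(s, p)
        assert np.linalg.norm(F) == pytest.approx(p.f0)

    def test_opposed_pullers_cancel(self):
        p = small_params()
        s = SimState.empty(p)
        half = p.N_max // 2
        s.occupied[[0, half]] = 1
        s.puller[[0, half]] = 1
        s.phi[[0, half]] = 0.3  # mirrored orientations about opposite normals
        assert np.allclose(total_ant_force(s, p), 0.0, atol=1e-12)

    def test_statics_zero_force(self):
        p = small_params()
        s = SimState.empty(p)
        s.theta = 0.4
        step_dynamics(s, p, F_ext_now=0.0, dt=p.dt)
        assert s.theta == 0.4 and s.v == 0.0

    def test_constant_force_closed_form(self):
        """One overdamped step: dtheta = F*dt/(gamma*l_rod), v = F/gamma."""
        p = small_params()
        s = SimState.empty(p)
        F = 5.0
        step_dynamics(s, p, F_ext_now=F, dt=p.dt)
        assert s.v == pytest.approx(F / p.gamma)
        assert s.theta == pytest.approx(F * p.dt / (p.gamma * p.l_rod))

    def test_local_force_is_tangential_by_default(self):
        p = small_params()
        s = SimState.empty(p)
        s.theta = 0.0
        s.F_ext_now = 3.0
        fl = local_force(s, p)
        # at theta=0 the tangent is +y
        assert fl == pytest.approx([0.0, 3.0])


class TestRunTrial:
    def test_no_ants_flat_theta(self):
        p = small_params(k_on=0.0)
        tr = run_trial(p, T_total=5.0, seed=1)
        assert np.all(tr.theta == 0.0)
        assert len(tr.events) == 0

    def test_same_seed_identical(self, default_params):
        a = run_trial(default_params, T_total=10.0, seed=9)
        b = run_trial(default_params, T_total=10.0, seed=9)
        assert np.array_equal(a.theta, b.theta)
        assert a.events.equals(b.events)

    def test_engines_bit_identical(self):
        """The compiled loop and the interpreted loop share one RNG stream
        and produce identical trajectories and event logs."""
        p = small_params()
        spec = PulseSpec(F_ext=0.3, duration_max=2.0, start_after=1.0)
        a = run_trial(p, spec, T_total=6.0, seed=7, engine="numba")
        b = run_trial(p, spec, T_total=6.0, seed=7, engine="python")
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.v, b.v)
        assert a.events.equals(b.events)
        assert np.array_equal(a.pulses.values, b.pulses.values)

    def test_occupancy_bounds(self, short_trajectory):
        tr = short_trajectory
        assert np.all(tr.N_attached >= 0)
        assert np.all(tr.N_attached <= tr.params.N_max)
        assert np.all(tr.G <= tr.N_attached)

    def test_overdamped_consistency(self, short_trajectory):
        """gamma*v equals the net tangential force at every sample, except
        within one dt of a stochastic event (the force is re-evaluated
        when the event executes, after the step's velocity was set)."""
        tr = short_trajectory
        dt = tr.t[1] - tr.t[0]
        ev_t = tr.events.t.to_numpy()
        has_event = np.zeros(len(tr.t), bool)
        idx = np.searchsorted(tr.t, ev_t - 1e-12)  # event in (t_i-dt, t_i]
        has_event[np.clip(idx, 0, len(tr.t) - 1)] = True
        quiet = ~has_event
        assert quiet.sum() > 0.3 * len(tr.t)
        np.testing.assert_allclose(
            tr.params.gamma * tr.v[quiet],
            (tr.F_ant_tang + tr.F_ext)[quiet],
            rtol=1e-9, atol=1e-9,
        )

    def test_single_site_stationary_occupancy(self):
        """N_max = 1 with only attach/detach is a two-state Markov chain
        with stationary occupancy k_on/(k_on + k_off)."""
        p = ModelParams(N_max=1, k_on=0.021, k_off=0.015, k_forget=0.0,
                        k_c=0.0, k_ori=0.0, attach_boost=1.0, gamma=3.0)
        tr = run_trial(p, T_total=40_000.0, seed=3, record_stride=100,
                       log_events=False)
        # brute-force oracle: 2-state generator [[-kon, kon], [koff, -koff]]
        Q = np.array([[-p.k_on, p.k_on], [p.k_off, -p.k_off]])
        pi = np.linalg.solve(
            np.vstack([Q.T[:-1], np.ones(2)]), np.array([0.0, 1.0])
        )
        occ = tr.N_attached.mean()
        # autocorrelation time 1/(kon+koff) ~ 28 s over 40000 s
        n_eff = 40_000.0 * (p.k_on + p.k_off)
        tol = 4.0 * math.sqrt(pi[1] * pi[0] / n_eff)
        assert occ == pytest.approx(pi[1], abs=tol)

    def test_mirror_symmetry_distributional(self):
        """Negating the initial displacement mirrors the theta ensemble."""
        p = ModelParams(N_max=12, attach_boost=1.0)
        finals = {s0: [] for s0 in (+1.0, -1.0)}
        for s0 in finals:
            for k in range(40):
                tr = run_trial(p, T_total=40.0, seed=1000 + k,
                               theta0=s0 * 0.5, record_stride=40,
                               log_events=False)
                finals[s0].append(tr.theta[-1])
        a = np.array(finals[+1.0])
        b = -np.array(finals[-1.0])
        # same seeds, mirrored initial condition: distributions must agree
        ks = stats.kstest(a, b)
        assert ks.pvalue > 1e-3
        sem = np.hypot(a.std() / np.sqrt(a.size), b.std() / np.sqrt(b.size))
        assert abs(a.mean() - b.mean()) < 4 * sem + 1e-6

    def test_ordered_speed_matches_meanfield(self, default_params):
        """In the ordered phase the microscopic mean speed tracks the
        mean-field spontaneous speed within 10%."""
        from antcargo.meanfield import MeanFieldParams, spontaneous_speed

        v0 = spontaneous_speed(MeanFieldParams(N=60))
        vals = []
        for s in range(4):
            tr = run_trial(default_params, T_total=200.0, seed=s,
                           record_stride=10, log_events=False)
            burn = len(tr.v) // 4
            vals.append(np.abs(tr.v[burn:]).mean())
        assert np.mean(vals) == pytest.approx(v0, rel=0.10)


class TestPulseAndOutcome:
    def test_no_crossing_no_pulse(self):
        p = small_params(k_on=0.0)  # cargo never moves
        spec = PulseSpec(F_ext=0.3, duration_max=2.0)
        tr = run_trial(p, spec, T_total=5.0, seed=0)
        assert len(tr.pulses) == 0
        assert np.all(tr.F_ext == 0.0)

    def test_pulse_opposes_motion_and_ends(self, default_params):
        spec = PulseSpec(F_ext=0.3, duration_max=1.0, max_pulses=1,
                         start_after=30.0, end_on_switch=False)
        tr = run_trial(default_params, spec, T_total=200.0, seed=5,
                       log_events=False)
        assert len(tr.pulses) == 1
        t0, t1 = float(tr.pulses.t_begin[0]), float(tr.pulses.t_end[0])
        assert t1 - t0 == pytest.approx(1.0, abs=0.05)
        during = (tr.t > t0 + 0.01) & (tr.t < t1 - 0.01)
        i_before = np.searchsorted(tr.t, t0) - 1
        v_before = tr.v[i_before]
        signs = np.sign(tr.F_ext[during])
        assert np.all(signs == -np.sign(v_before))
        after = tr.t > t1 + 0.01
        assert np.all(tr.F_ext[after] == 0.0)

    def test_classify_resist_without_reversal(self, default_params):
        # a tiny force cannot reverse the ordered cargo
        spec = PulseSpec(F_ext=0.02, duration_max=2.0, max_pulses=1,
                         start_after=30.0, end_on_switch=False)
        tr = run_trial(default_params, spec, T_total=250.0, seed=2,
                       log_events=False, stop_after_pulse=3.0)
        assert len(tr.pulses) == 1
        ev = classify_outcome(tr)
        assert ev.outcome == "resist"
        assert ev.duration == pytest.approx(
            float(tr.pulses.t_end[0]) - float(tr.pulses.t_begin[0])
        )

    def test_classify_switch_on_clean_reversal(self):
        """A strong opposing pulse reverses an intermediate group; the
        switch time is the first sustained omega reversal."""
        p = ModelParams().with_group_size(20)
        spec = PulseSpec(F_ext=1.0, duration_max=8.0, max_pulses=1,
                         start_after=30.0, end_on_switch=False)
        tr = run_trial(p, spec, T_total=280.0, seed=4, log_events=False,
                       stop_after_pulse=3.0)
        assert len(tr.pulses) == 1
        ev = classify_outcome(tr)
        assert ev.outcome == "switch"
        assert tr.pulses.t_begin[0] < ev.t_switch <= tr.pulses.t_end[0]

    def test_window_outside_trajectory_rejected(self, short_trajectory):
        with pytest.raises(ValueError):
            classify_outcome(short_trajectory, pulse=(10.0, 99.0))
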