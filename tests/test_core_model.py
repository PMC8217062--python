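"""The lumped energy balance and its piecewise-analytic solution.

Closed-form results are cross-checked against an independent fixed-step RK4
integration of the governing ODE and against one-dimensional flux-balance
root finding, never against the analytic expressions themselves.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from lithotherm import (
    AnalyticCurve,
    LaserSchedule,
    SystemConfig,
    TemperatureTrace,
    UnboundedHeatingError,
    delta_T_after_firing,
    heat_load,
    ode_oracle,
    temperature_at,
    temperature_trace,
)
from conftest import random_config, random_schedule

RHO_C = 1.00e3 * 4.18e3


class TestHeatLoad:
    def test_no_sources_no_gradients_gives_bath_temperature(self, set_a_cfg):
        cfg = set_a_cfg.replace(Tin=set_a_cfg.T0)
        tstar, _ = heat_load(cfg, 0.0)
        assert tstar == pytest.approx(cfg.T0)

    def test_still_fluid_40w_plateau_and_rise_time_match_ode(self, set_a_cfg):
        """Plateau and 63.2%-rise time read off an RK4 integration of the balance."""
        tstar, tau = heat_load(set_a_cfg, 40.0)
        assert tstar == pytest.approx(set_a_cfg.T0 + 40.0 / 1.15, rel=1e-12)
        assert tau == pytest.approx(RHO_C * 5.89e-6 / 1.15, rel=1e-3)
        # independent read-off: integrate far past equilibration
        sched = LaserSchedule.single(0.0, 400.0, 40.0)
        grid = np.arange(0.0, 400.001, 0.01)
        ode = ode_oracle(set_a_cfg, sched, grid, dt=1e-3)
        assert ode.temps[-1] == pytest.approx(tstar, abs=1e-3)
        target = set_a_cfg.T0 + (1 - math.exp(-1)) * (tstar - set_a_cfg.T0)
        i = int(np.argmax(ode.temps >= target))
        assert grid[i] == pytest.approx(tau, abs=0.02)

    def test_cold_high_flow_plateau_from_flux_balance_root(self, set_a_cfg):
        """W = rho*c*Q*(T-Tin) + beta*(T-T0) solved independently by brentq."""
        cfg = set_a_cfg.replace(Q=35e-6 / 60.0, Tin=18.0)
        tstar, _ = heat_load(cfg, 40.0)
        root = brentq(
            lambda T: 40.0 - RHO_C * cfg.Q * (T - 18.0) - 1.15 * (T - 37.0), 0.0, 100.0
        )
        assert tstar == pytest.approx(root, abs=1e-9)
        assert tstar < 37.0  # plateaus below body temperature

    def test_no_sink_has_no_steady_state(self):
        cfg = SystemConfig.from_clinical(volume_ml=38.3, t0_c=22.0, beta_w_per_c=0.0)
        with pytest.raises(UnboundedHeatingError):
            heat_load(cfg, 40.0)

    def test_steady_state_independent_of_volume(self, set_a_cfg):
        stars = {
            heat_load(set_a_cfg.replace(V=v * 1e-6), 40.0)[0] for v in (5.89, 38.3, 100.0)
        }
        assert len({round(s, 12) for s in stars}) == 1

    def test_time_constant_proportional_to_volume(self, set_a_cfg):
        _, tau1 = heat_load(set_a_cfg, 40.0)
        _, tau2 = heat_load(set_a_cfg.replace(V=2 * set_a_cfg.V), 40.0)
        assert tau2 / tau1 == pytest.approx(2.0, rel=1e-12)


class TestTemperatureAt:
    def test_initial_condition(self, set_b_cfg, burst_40w):
        assert temperature_at(set_b_cfg, burst_40w, 0.0) == set_b_cfg.T0
        assert temperature_at(set_b_cfg, burst_40w, 0.0, T_init=30.0) == 30.0

    def test_adiabatic_limit_is_linear_heating(self, burst_40w):
        cfg = SystemConfig.from_clinical(volume_ml=38.3, t0_c=22.0, beta_w_per_c=0.0)
        sched = LaserSchedule.single(0.0, 60.0, 40.0)
        rise = temperature_at(cfg, sched, 60.0) - cfg.T0
        assert rise == pytest.approx(40.0 * 60.0 / (RHO_C * 38.3e-6), rel=1e-12)

    def test_still_fluid_burst_matches_ode_oracle(self, set_b_cfg, burst_40w):
        t_end = temperature_at(set_b_cfg, burst_40w, 80.0)
        ode = ode_oracle(set_b_cfg, burst_40w, np.array([0.0, 80.0]), dt=1e-3)
        assert t_end == pytest.approx(ode.temps[-1], abs=1e-3)
        assert t_end == pytest.approx(33.74, abs=0.02)

    def test_negative_time_rejected(self, set_b_cfg, burst_40w):
        with pytest.raises(ValueError):
            temperature_at(set_b_cfg, burst_40w, -1.0)


class TestTemperatureTrace:
    def test_matches_pointwise_evaluation(self, set_b_cfg, burst_40w):
        grid = np.array([0.0, 30.0])
        tr = temperature_trace(set_b_cfg, burst_40w, grid)
        assert tr.temps[0] == temperature_at(set_b_cfg, burst_40w, 0.0)
        assert tr.temps[1] == temperature_at(set_b_cfg, burst_40w, 30.0)

    def test_default_grid_covers_standard_protocol(self, set_b_cfg, burst_40w):
        tr = temperature_trace(set_b_cfg, burst_40w)
        assert tr.times[0] == 0.0
        assert tr.times[-1] == pytest.approx(100.0)
        assert len(tr) == 1001

    def test_monotone_towards_phase_steady_state(self, set_a_cfg, burst_40w):
        cfg = set_a_cfg.replace(Q=14.5e-6 / 60.0)
        tr = temperature_trace(cfg, burst_40w)
        on = (tr.times >= 20.0) & (tr.times <= 80.0)
        assert np.all(np.diff(tr.temps[on]) >= 0)  # rising towards hot steady state
        off = tr.times >= 80.0
        assert np.all(np.diff(tr.temps[off]) <= 0)  # decaying after switch-off

    def test_irrigated_burst_matches_ode_everywhere(self, set_a_cfg, default_grid):
        cfg = set_a_cfg.replace(Q=14.5e-6 / 60.0)
        sched = LaserSchedule.single(20.0, 80.0, 40.0)
        an = temperature_trace(cfg, sched, default_grid)
        ode = ode_oracle(cfg, sched, default_grid, dt=1e-3)
        assert np.max(np.abs(an.temps - ode.temps)) < 1e-3

    def test_empty_grid_rejected(self, set_b_cfg, burst_40w):
        with pytest.raises(ValueError):
            temperature_trace(set_b_cfg, burst_40w, np.array([]))


class TestOdeOracle:
    def test_equilibrium_input_stays_constant(self, set_b_cfg):
        tr = ode_oracle(set_b_cfg, LaserSchedule(intervals=()), np.arange(0.0, 50.0, 1.0))
        assert np.max(np.abs(tr.temps - set_b_cfg.T0)) < 1e-12

    def test_fourth_order_convergence(self):
        """Halving the step shrinks the deviation by about 2^4."""
        # small vessel and strong losses so truncation error is measurable
        cfg = SystemConfig.from_clinical(
            volume_ml=1.0, t0_c=37.0, beta_w_per_c=2.0, flow_ml_min=40.0, t_in_c=23.0
        )
        sched = LaserSchedule.single(2.0, 8.0, 40.0)  # switches on the dt grid
        grid = np.arange(0.0, 10.0001, 0.5)
        an = temperature_trace(cfg, sched, grid)
        devs = [
            np.max(np.abs(ode_oracle(cfg, sched, grid, dt=dt).temps - an.temps))
            for dt in (0.5, 0.25)
        ]
        ratio = devs[0] / devs[1]
        assert 8.0 < ratio < 32.0

    def test_agrees_with_analytic_under_irrigation(self, set_b_cfg, default_grid):
        cfg = set_b_cfg.replace(Q=20e-6 / 60.0)
        sched = LaserSchedule.single(20.0, 80.0, 40.0)
        an = temperature_trace(cfg, sched, default_grid)
        ode = ode_oracle(cfg, sched, default_grid, dt=1e-3)
        assert np.max(np.abs(an.temps - ode.temps)) < 1e-3


class TestDeltaTAfterFiring:
    def test_zero_without_sources_or_gradients(self, set_b_cfg):
        cfg = set_b_cfg.replace(Tin=set_b_cfg.T0)
        assert delta_T_after_firing(cfg, 0.0, 60.0) == pytest.approx(0.0, abs=1e-12)

    def test_positive_when_irrigation_matches_bath(self, set_b_cfg):
        cfg = set_b_cfg.replace(Tin=set_b_cfg.T0, Q=40e-6 / 60.0)
        for w in (5.0, 20.0, 40.0):
            assert delta_T_after_firing(cfg, w, 60.0) > 0

    def test_cold_irrigation_case_matches_ode_oracle(self):
        cfg = SystemConfig.from_clinical(
            volume_ml=30.0, t0_c=37.0, beta_w_per_c=1.15, flow_ml_min=20.0, t_in_c=23.0
        )
        d = delta_T_after_firing(cfg, 20.0, 60.0)
        ode = ode_oracle(
            cfg, LaserSchedule.single(0.0, 60.0, 20.0), np.array([0.0, 60.0]), dt=1e-3
        )
        assert d == pytest.approx(ode.temps[-1] - 37.0, abs=1e-3)

    def test_monotone_in_power_flow_and_volume(self, set_a_cfg):
        cfg = set_a_cfg.replace(Q=20e-6 / 60.0)
        dws = [delta_T_after_firing(cfg, w, 60.0) for w in (10.0, 20.0, 40.0)]
        assert dws[0] < dws[1] < dws[2]
        dqs = [
            delta_T_after_firing(cfg.replace(Q=q * 1e-6 / 60.0), 40.0, 60.0)
            for q in (0.0, 20.0, 40.0)
        ]
        assert dqs[0] >= dqs[1] >= dqs[2]
        dvs = [
            delta_T_after_firing(cfg.replace(V=v * 1e-6), 40.0, 60.0)
            for v in (5.89, 38.3, 100.0)
        ]
        assert dvs[0] >= dvs[1] >= dvs[2]


class TestInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_analytic_matches_rk4_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        cfg = random_config(rng)
        sched = random_schedule(rng)
        grid = np.arange(0.0, 200.0001, 0.5)
        an = temperature_trace(cfg, sched, grid)
        ode = ode_oracle(cfg, sched, grid, dt=1e-3)
        assert np.max(np.abs(an.temps - ode.temps)) < 1e-2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_single_burst_bounded_by_steady_states(self, seed):
        rng = np.random.default_rng(seed)
        cfg = random_config(rng)
        on, off, w = 10.0, float(rng.uniform(20.0, 120.0)), float(rng.uniform(5.0, 60.0))
        sched = LaserSchedule.single(on, off, w)
        star_off, _ = heat_load(cfg, 0.0)
        star_on, _ = heat_load(cfg, w)
        lo = min(cfg.T0, star_off, star_on) - 1e-9
        hi = max(cfg.T0, star_off, star_on) + 1e-9
        tr = temperature_trace(cfg, sched, np.arange(0.0, 200.0, 0.25))
        assert np.all(tr.temps >= lo) and np.all(tr.temps <= hi)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_continuity_at_every_switch(self, seed):
        rng = np.random.default_rng(seed)
        cfg = random_config(rng)
        sched = random_schedule(rng)
        curve = AnalyticCurve(cfg, sched)
        eps = 1e-9
        for on, off, _ in sched.intervals:
            for t in (on, off):
                if t <= eps:
                    continue
                assert curve(t + eps) == pytest.approx(curve(t - eps), abs=1e-6)


class TestTypes:
    def test_trace_validation(self):
        with pytest.raises(ValueError):
            TemperatureTrace(times=np.array([0.0, 0.0]), temps=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            TemperatureTrace(times=np.array([0.0]), temps=np.array([1.0]))
        with pytest.raises(ValueError):
            TemperatureTrace(times=np.array([0.0, 1.0]), temps=np.array([1.0]))

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            LaserSchedule(intervals=((10.0, 5.0, 40.0),))
        with pytest.raises(ValueError):
            LaserSchedule(intervals=((0.0, 10.0, 40.0), (5.0, 15.0, 40.0)))
        with pytest.raises(ValueError):
            LaserSchedule(intervals=((0.0, 10.0, -1.0),))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SystemConfig(V=-1e-6, T0=37.0, beta=1.0)
        with pytest.raises(ValueError):
            SystemConfig(V=1e-6, T0=37.0, beta=-0.5)
        with pytest.raises(ValueError):
            SystemConfig(V=1e-6, T0=math.nan, beta=1.0)
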