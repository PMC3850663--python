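"""Integration engine: reduced path, DAE path, events, reactions, energy."""

import math

import numpy as np
import pytest

import cervixsim as cx
from cervixsim.dynamics import (
    IntegrationMethod,
    SolverConfig,
    integrate_full_dae,
    reduced_rhs,
)
from cervixsim.kinematics import ReducedState, full_state, tangent
from cervixsim.model_core import constraint_matrix, load_vector

L = 0.0225


class TestReducedRhs:
    def test_initial_acceleration_under_full_traction(self, params):
        """The bare initial acceleration is ~2.4e4 rad/s^2 — the stiffness
        that forces an implicit solver and motivates the ramp protocol."""
        cfg = cx.ControllerConfig()
        t = 3600.0  # post-ramp: full traction, springs clamped at zero
        tdd = reduced_rhs(ReducedState(0.0, 0.0), t, cfg, params)
        expected = (
            L * cx.applied_traction(t, cfg, params)
            - params.quarter_mass * params.g * L / 2
        ) / params.pivot_inertia
        assert tdd == pytest.approx(expected, rel=1e-12)
        assert tdd == pytest.approx(2.363e4, rel=5e-3)

    def test_rest_is_equilibrium_without_loads(self):
        p = cx.ModelParameters(g=0.0, traction_mass=0.0)
        assert reduced_rhs(ReducedState(0.0, 0.0), 100.0, cx.ControllerConfig(), p) == 0.0

    def test_domain_guard(self, params):
        with pytest.raises(ValueError, match="domain"):
            reduced_rhs(ReducedState(3.0, 0.0), 10.0, cx.ControllerConfig(), params)

    def test_reaction_directions_never_enter_the_projected_equation(self, params):
        # J^T C^T f = 0 for any reaction f: reactions are workless, so the
        # projected dynamics are independent of them.
        rng = np.random.default_rng(3)
        for theta in rng.uniform(0, math.pi / 2, 20):
            J = tangent(theta, params)
            CT = constraint_matrix(cx.solve_configuration(theta, params), params)
            f = rng.standard_normal(3)
            assert abs(J @ (CT @ f)) < 1e-10 * max(1.0, np.linalg.norm(f))


class TestRecoverReactions:
    def test_unloaded_weightless_rest_has_no_reactions(self):
        p = cx.ModelParameters(g=0.0)
        state = full_state(ReducedState(0.0, 0.0), p)
        reac = cx.recover_reactions(state, 0.0, cx.LoadState(), p)
        assert reac.as_array == pytest.approx((0.0, 0.0, 0.0), abs=1e-15)

    def test_reconstruction_residual_is_negligible(self, params):
        rng = np.random.default_rng(11)
        for _ in range(30):
            theta = rng.uniform(0.01, math.pi / 2 - 0.01)
            thetadot = rng.uniform(0, 1e-3)
            state = full_state(ReducedState(theta, thetadot), params)
            loads = cx.LoadState(
                K1=rng.uniform(0, 1), K2=rng.uniform(0, 1e4),
                F_traction=rng.uniform(0, 1.3),
            )
            # acceleration consistent with these loads
            J = tangent(theta, params)
            tdd = float(J @ load_vector(state, loads, params)) / params.pivot_inertia
            reac = cx.recover_reactions(state, tdd, loads, params)
            CT = constraint_matrix(state, params)
            M = cx.mass_matrix(params)
            qdd = np.array(
                [
                    L * math.cos(theta) * thetadot**2 + L * math.sin(theta) * tdd,
                    -L * math.sin(theta) * thetadot**2 + L * math.cos(theta) * tdd,
                    tdd,
                    -tdd,
                ]
            )
            rhs = load_vector(state, loads, params) - M @ qdd
            resid = np.linalg.norm(CT @ reac.as_array - rhs)
            assert resid < 1e-8 * max(1.0, np.linalg.norm(rhs))


class TestDefaultRun:
    def test_reaches_published_endpoints_near_seven_hours(self, pin_result):
        s = pin_result.summary
        assert s["final_diameter_cm"] == pytest.approx(4.50, rel=5e-3)
        assert s["final_effacement_cm"] == pytest.approx(2.25, rel=5e-3)
        assert 6.5 <= s["final_time_hr"] <= 7.0 + 1e-9

    def test_trajectory_is_monotone_and_constraint_consistent(self, pin_result):
        ser = pin_result.series
        assert np.all(np.diff(ser["dilation_diameter_cm"]) >= -1e-9)
        assert np.all(np.diff(ser["effacement_cm"]) >= -1e-9)
        assert ser["constraint_residual"].max() < 1e-12  # exact by construction

    def test_steady_tracking_holds_the_setpoint(self, pin_result):
        rate = pin_result.summary["steady_tracking_rate_cm_per_hr"]
        assert rate == pytest.approx(0.692, rel=0.01)

    def test_traction_trace_ramps_to_published_value(self, pin_result):
        ser = pin_result.series
        post = ser[ser["t_s"] >= 1800.0]["F_traction_N"]
        assert np.all(np.abs(post - 1.22625) < 1e-12)

    def test_zero_load_scenario_stays_closed(self):
        p = cx.ModelParameters(g=0.0, traction_mass=0.0)
        res = cx.integrate(p, cx.ControllerConfig(), SolverConfig(t_end=3600.0))
        assert res.summary["final_diameter_cm"] == 0.0
        assert res.summary["termination_reason"] == "t_end_reached"
        assert np.all(res.series["dilation_diameter_cm"] == 0.0)

    def test_gravity_holds_the_stop_until_traction_builds(self, pin_result):
        # before lift-off (~190 s) the ramped traction moment is below the
        # weight moment and the closed cervix does not move
        early = pin_result.series[pin_result.series["t_s"] <= 180.0]
        assert np.all(early["theta_rad"] == 0.0)


class TestEventTermination:
    def test_event_fires_at_configured_diameter(self, params, fast_controller):
        solver = SolverConfig(termination_diameter=0.03, t_end=7200.0)
        res = cx.integrate(params, fast_controller, solver)
        s = res.summary
        assert s["termination_reason"] == "termination_diameter_reached"
        assert s["final_diameter_cm"] == pytest.approx(3.0, abs=1e-4)
        # geometric coupling: effacement = l sin(theta) at the event angle
        theta = math.acos(1.0 - 0.03 / (2 * L))
        assert s["final_effacement_cm"] == pytest.approx(
            100 * L * math.sin(theta), abs=1e-4
        )

    def test_unreachable_termination_diameter_is_rejected(self, params):
        with pytest.raises(ValueError, match="termination_diameter"):
            cx.integrate(
                params, cx.ControllerConfig(), SolverConfig(termination_diameter=0.05)
            )

    def test_unclamped_controller_is_rejected(self, params):
        cfg = cx.ControllerConfig(clamp_nonnegative=False)
        with pytest.raises(ValueError, match="clamp_nonnegative"):
            cx.integrate(params, cfg)


class TestEnergyAudit:
    def test_power_balance_closes_along_the_trajectory(self, pin_result, params):
        """Projected power equals the rate of change of kinetic energy; the
        residual integrates to a vanishing fraction of the traction work."""
        cfg = cx.ControllerConfig()
        ser = pin_result.series
        t = ser["t_s"].to_numpy()
        theta = ser["theta_rad"].to_numpy()
        thetadot = ser["theta_dot_rad_per_s"].to_numpy()
        tdd = np.array(
            [
                reduced_rhs(ReducedState(th, thd), ti, cfg, params, 1e-4)
                for th, thd, ti in zip(theta, thetadot, t)
            ]
        )
        m33 = params.pivot_inertia
        power = m33 * tdd * thetadot  # = (J^T F) theta_dot along the solution
        ke = 0.5 * m33 * thetadot**2
        residual = abs(np.trapezoid(power, t) - (ke[-1] - ke[0]))
        traction_work = np.trapezoid(
            ser["F_traction_N"].to_numpy()
            * L * np.cos(theta) * thetadot,
            t,
        )
        assert residual < 1e-3 * traction_work


class TestFullDae:
    def test_short_run_matches_reduced_path(self, params, fast_controller):
        solver = SolverConfig(t_end=1800.0, abs_tol=1e-6, rel_tol=1e-6)
        red = cx.integrate(params, fast_controller, solver)
        dae = integrate_full_dae(params, fast_controller, solver)
        grid = np.arange(0.0, 1800.0, 10.0)
        a = np.interp(grid, red.series["t_s"], red.series["theta_rad"])
        b = np.interp(grid, dae.series["t_s"], dae.series["theta_rad"])
        assert np.max(np.abs(a - b)) / (math.pi / 2) < 1e-5
        assert dae.series["constraint_residual"].max() < 1e-6

    def test_zero_load_rest_in_both_modes(self):
        p = cx.ModelParameters(g=0.0, traction_mass=0.0)
        solver = SolverConfig(t_end=600.0)
        red = cx.integrate(p, cx.ControllerConfig(), solver)
        dae = integrate_full_dae(p, cx.ControllerConfig(), solver)
        assert np.all(red.series["dilation_diameter_cm"] == 0.0)
        assert np.all(dae.series["dilation_diameter_cm"] == 0.0)

    def test_method_dispatch(self, params, fast_controller):
        solver = SolverConfig(t_end=600.0, method=IntegrationMethod.FULL_DAE)
        res = cx.integrate(params, fast_controller, solver)
        assert res.method is IntegrationMethod.FULL_DAE


class TestSolverConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [
            {"abs_tol": 0.0},
            {"t_end": -1.0},
            {"output_interval": 0.0},
            {"termination_diameter": -0.01},
            {"feedback_smoothing": -1.0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)
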