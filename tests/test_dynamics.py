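import numpy as np
import pytest

from gustfall.bodies_aero import (BodySpec, LinearDragClosure,
                                  QuadraticDragClosure, ZeroClosure,
                                  calibrate_closure_to_terminal_velocity)
from gustfall.dynamics import (BodyState, FrameSpec, StiffnessError,
                               equivalence_deviation, rhs_inertial_frame,
                               rhs_tunnel_frame, simulate,
                               transform_kinematics)
from gustfall.gusts import GustProfile
from gustfall.scales import AIR, X_UP

Y = np.array([0.0, 1.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])


class TestTransformKinematics:
    def test_static_frame_is_identity(self):
        u, a = transform_kinematics([1, 2, 3], [4, 5, 6], [7, 8, 9],
                                    np.zeros(3), np.zeros(3), np.zeros(3),
                                    np.zeros(3))
        assert u == pytest.approx([4, 5, 6])
        assert a == pytest.approx([7, 8, 9])

    def test_coriolis_term(self):
        u, a = transform_kinematics(np.zeros(3), X_UP, np.zeros(3),
                                    np.zeros(3), Z, np.zeros(3), np.zeros(3))
        assert a == pytest.approx(2 * np.cross(Z, X_UP))  # = 2 y_hat

    def test_pure_translation(self):
        u, a = transform_kinematics([0, 0, 0], [1, 0, 0], [0.5, 0, 0],
                                    [0, 2, 0], np.zeros(3), [0, 3, 0],
                                    np.zeros(3))
        assert u == pytest.approx([1, 2, 0])
        assert a == pytest.approx([0.5, 3, 0])

    def test_centripetal_term(self):
        # x' = y_hat, omega = z_hat: centripetal acceleration -y_hat
        u, a = transform_kinematics(Y, np.zeros(3), np.zeros(3),
                                    np.zeros(3), Z, np.zeros(3), np.zeros(3))
        assert a == pytest.approx(-Y)


def hover_rhs_args(body, closure, gust=None):
    u_t = 0.38
    inflow = u_t * X_UP
    y0 = BodyState.at_rest().pack()
    return y0, body, AIR, closure, gust, inflow


class TestRightHandSides:
    def test_hover_is_equilibrium(self, dense_body, linear_closure_ut038):
        y0, *args = hover_rhs_args(dense_body, linear_closure_ut038)
        dy = rhs_tunnel_frame(0.0, y0, *args)
        assert dy == pytest.approx(np.zeros(13), abs=1e-12)

    def test_frames_agree_without_gust(self, dense_body, linear_closure_ut038):
        y = BodyState(position=[0.1, 0.2, 0.0], velocity=[0.05, -0.1, 0.0],
                      quaternion=[1, 0, 0, 0], omega_body=[0, 0, 0.3]).pack()
        args = (dense_body, AIR, linear_closure_ut038, None, 0.38 * X_UP)
        assert rhs_tunnel_frame(0.0, y, *args) == pytest.approx(
            rhs_inertial_frame(0.0, y, *args))

    def test_gust_force_vanishes_at_neutral_buoyancy(self, linear_closure_ut038):
        body = BodySpec(mass=1e-6, mean_density=AIR.density, length=0.01,
                        inertia=np.diag([1e-11] * 3))
        gust = GustProfile.ramp(t0=-1.0, dt=10.0, dv=5.0)  # active at t=0
        y0 = BodyState.at_rest().pack()
        with_gust = rhs_tunnel_frame(0.0, y0, body, AIR, linear_closure_ut038,
                                     gust, 0.38 * X_UP)
        without = rhs_tunnel_frame(0.0, y0, body, AIR, linear_closure_ut038,
                                   None, 0.38 * X_UP)
        assert with_gust == pytest.approx(without, abs=0)

    def test_rightward_gust_accelerates_bottom_heavy_body_clockwise(
            self, bottom_heavy_body):
        # upright body, gust acceleration towards +y: angular acceleration
        # about +z, i.e. clockwise in the camera view (z into the plane)
        gust = GustProfile.ramp(t0=-1.0, dt=10.0, dv=50.0)
        y0 = BodyState.at_rest().pack()
        dy = rhs_tunnel_frame(0.0, y0, bottom_heavy_body, AIR, ZeroClosure(),
                              gust, np.zeros(3))
        omega_dot = dy[10:13]
        assert omega_dot[2] > 0
        assert omega_dot[:2] == pytest.approx(np.zeros(2), abs=1e-15)
        # and the reduced gust force pushes the body the opposite way (-y)
        assert dy[4] < 0

    def test_upright_buoyancy_torque_restores(self, bottom_heavy_body):
        # clockwise tilt (theta > 0) must produce a counter-clockwise
        # (negative z) angular acceleration: the diaspore rights itself
        y = BodyState.at_rest().tilted(0.3).pack()
        dy = rhs_tunnel_frame(0.0, y, bottom_heavy_body, AIR, ZeroClosure(),
                              None, np.zeros(3))
        assert dy[12] < 0


class TestIntegrationOracles:
    def test_ballistic_fall_matches_closed_form(self, dense_body, air):
        g_star = dense_body.reduced_gravity_in(air)
        traj = simulate(dense_body, air, ZeroClosure(), FrameSpec("tunnel"),
                        BodyState.at_rest(), (0.0, 1.0),
                        t_eval=np.linspace(0, 1, 51))
        exact = -0.5 * g_star * traj.t**2
        assert traj.position[:, 0] == pytest.approx(exact, abs=1e-8)

    def test_linear_drag_velocity_relaxation(self, dense_body, air,
                                             linear_closure_ut038):
        c = linear_closure_ut038.c
        tau = dense_body.mass / c
        u_t = dense_body.mass * dense_body.reduced_gravity_in(air) / c
        traj = simulate(dense_body, air, linear_closure_ut038,
                        FrameSpec("tunnel"), BodyState.at_rest(), (0.0, 1.0),
                        t_eval=np.linspace(0, 1, 51))
        exact = -u_t * (1.0 - np.exp(-traj.t / tau))
        assert np.max(np.abs(traj.velocity[:, 0] - exact)) < 1e-7 * u_t

    def test_hover_is_a_fixed_point_over_ten_seconds(self, dense_body, air,
                                                     linear_closure_ut038):
        u_t = 0.38
        frame = FrameSpec("tunnel", inflow=u_t * X_UP)
        traj = simulate(dense_body, air, linear_closure_ut038, frame,
                        BodyState.at_rest(), (0.0, 10.0),
                        t_eval=np.linspace(0, 10, 101))
        assert np.max(np.abs(traj.position)) < 1e-10
        assert np.max(np.abs(traj.velocity)) < 1e-10

    def test_energy_conserved_in_free_flight(self, dense_body, air):
        # no aerodynamic force, no gust: kinetic + reduced-gravity potential
        g_star = dense_body.reduced_gravity_in(air)
        state0 = BodyState(position=np.zeros(3), velocity=[0.3, 0.2, 0.0],
                           quaternion=[1, 0, 0, 0], omega_body=[0, 0, 1.0])
        traj = simulate(dense_body, air, ZeroClosure(), FrameSpec("tunnel"),
                        state0, (0.0, 2.0), t_eval=np.linspace(0, 2, 41))
        e = (0.5 * np.sum(traj.velocity**2, axis=1)
             + g_star * traj.position[:, 0])
        assert np.max(np.abs(e - e[0])) < 1e-8 * max(1.0, abs(e[0]))

    def test_invalid_t_span_rejected(self, dense_body, air):
        with pytest.raises(ValueError):
            simulate(dense_body, air, ZeroClosure(), FrameSpec("tunnel"),
                     BodyState.at_rest(), (1.0, 0.0))


class TestStepGustImpulse:
    def test_post_step_relative_velocity_decay(self, dense_body, air,
                                               linear_closure_ut038):
        # tunnel frame: after a step of v1 in the far-field velocity the
        # relative horizontal velocity is -(1 - rho) v1 exp(-t/tau)
        v1, t_step = 0.5, 0.5
        gust = GustProfile.step(v1, t0=t_step)
        frame = FrameSpec("tunnel", gust, inflow=0.38 * X_UP)
        traj = simulate(dense_body, air, linear_closure_ut038, frame,
                        BodyState.at_rest(), (0.0, 3.0),
                        t_eval=np.linspace(0, 3, 301))
        rho = air.density / dense_body.mean_density
        tau = dense_body.mass / linear_closure_ut038.c
        mask = traj.t >= t_step
        exact = -(1.0 - rho) * v1 * np.exp(-(traj.t[mask] - t_step) / tau)
        assert np.max(np.abs(traj.velocity[mask, 1] - exact)) < 1e-7 * v1

    def test_linearity_in_amplitude_and_density_excess(self, air):
        # linear closure: horizontal response scales with gust amplitude
        # and with (1 - rho_f/rho_b)
        def response(v1, rho_b):
            body = BodySpec(mass=1e-6, mean_density=rho_b, length=0.01,
                            inertia=np.diag([1e-11] * 3))
            cl = LinearDragClosure(c=2e-5)
            gust = GustProfile.step(v1, t0=0.2)
            traj = simulate(body, air, cl,
                            FrameSpec("tunnel", gust), BodyState.at_rest(),
                            (0.0, 1.0), t_eval=np.linspace(0, 1, 101))
            return traj.velocity[:, 1]

        # three amplitudes at fixed density: superposition
        r1, r2, r3 = response(0.2, 600.0), response(0.4, 600.0), response(0.6, 600.0)
        # superposition holds to the integrator tolerance (velocities O(0.1))
        assert r2 == pytest.approx(2 * r1, abs=1e-8)
        assert r3 == pytest.approx(3 * r1, abs=1e-8)
        # density excess scaling at fixed amplitude
        f600 = 1 - air.density / 600.0
        f2p4 = 1 - air.density / 2.4
        assert response(0.4, 2.4) == pytest.approx(
            r2 * f2p4 / f600, abs=1e-8)


class TestNeutralBuoyancyNull:
    def test_gusted_run_is_bitwise_identical_to_ungusted(self, air):
        body = BodySpec(mass=1e-6, mean_density=air.density, length=0.01,
                        inertia=np.diag([1e-11] * 3))
        cl = LinearDragClosure(c=2e-5)
        t_eval = np.linspace(0, 2, 201)
        gusted = simulate(body, air, cl,
                          FrameSpec("tunnel", GustProfile.step(0.7, t0=0.5)),
                          BodyState.at_rest(), (0.0, 2.0), t_eval=t_eval)
        quiet = simulate(body, air, cl, FrameSpec("tunnel"),
                         BodyState.at_rest(), (0.0, 2.0), t_eval=t_eval)
        assert np.array_equal(gusted.position, quiet.position)
        assert np.array_equal(gusted.velocity, quiet.velocity)
        assert np.array_equal(gusted.quaternion, quiet.quaternion)
        assert np.array_equal(gusted.omega_body, quiet.omega_body)


class TestRighting:
    def test_tilted_bottom_heavy_body_returns_upright(self, bottom_heavy_body,
                                                      air):
        closure = calibrate_closure_to_terminal_velocity(
            0.38, bottom_heavy_body, air, "quadratic", c_omega=1e-10)
        frame = FrameSpec("tunnel", inflow=0.38 * X_UP)
        state0 = BodyState.at_rest().tilted(0.3)
        traj = simulate(bottom_heavy_body, air, closure, frame, state0,
                        (0.0, 6.0), t_eval=np.linspace(0, 6, 301))
        theta = traj.tilt_angle()
        assert abs(theta[0]) == pytest.approx(0.3, abs=1e-9)
        assert abs(theta[-1]) < 0.01


class TestAltitudeGainMechanism:
    def test_quadratic_closure_gains_height_linear_does_not(
            self, bottom_heavy_body, air):
        gust = GustProfile.step(0.5, t0=0.2)
        frame = FrameSpec("tunnel", gust, inflow=0.38 * X_UP)
        t_eval = np.linspace(0, 3, 301)
        quad = calibrate_closure_to_terminal_velocity(
            0.38, bottom_heavy_body, air, "quadratic", c_omega=1e-10)
        lin = calibrate_closure_to_terminal_velocity(
            0.38, bottom_heavy_body, air, "linear", c_omega=1e-10)
        h_quad = simulate(bottom_heavy_body, air, quad, frame,
                          BodyState.at_rest(), (0.0, 3.0),
                          t_eval=t_eval).position[:, 0]
        h_lin = simulate(bottom_heavy_body, air, lin, frame,
                         BodyState.at_rest(), (0.0, 3.0),
                         t_eval=t_eval).position[:, 0]
        assert np.max(h_quad) > 1e-4          # transient rise, metres
        assert np.max(np.abs(h_lin)) < 1e-12  # isotropic linear drag: none


class TestFrameEquivalence:
    def test_no_gust_gives_zero_deviation(self, dense_body, air,
                                          linear_closure_ut038):
        t_eval = np.linspace(0, 2, 101)
        kw = dict(t_eval=t_eval)
        ti = simulate(dense_body, air, linear_closure_ut038,
                      FrameSpec("inertial", inflow=0.38 * X_UP),
                      BodyState.at_rest(), (0, 2.0), **kw)
        tt = simulate(dense_body, air, linear_closure_ut038,
                      FrameSpec("tunnel", inflow=0.38 * X_UP),
                      BodyState.at_rest(), (0, 2.0), **kw)
        dx, du = equivalence_deviation(ti, tt, None)
        assert dx == 0.0 and du == 0.0

    def test_deviation_shrinks_with_tolerance(self, dense_body, air):
        closure = QuadraticDragClosure(C_D=0.6, area=1e-4)
        gust = GustProfile.ramp(t0=0.3, dt=0.4, dv=0.8)
        t_eval = np.linspace(0, 2, 101)

        def dev(rtol):
            runs = {}
            for tag in ("inertial", "tunnel"):
                runs[tag] = simulate(
                    dense_body, air, closure,
                    FrameSpec(tag, gust, inflow=0.38 * X_UP),
                    BodyState.at_rest(), (0, 2.0), t_eval=t_eval,
                    rtol=rtol, atol=rtol * 1e-2)
            return max(equivalence_deviation(runs["inertial"],
                                             runs["tunnel"], gust))

        loose, tight = dev(1e-8), dev(1e-10)
        assert tight < loose / 10

    def test_mismatched_grids_rejected(self, dense_body, air,
                                       linear_closure_ut038):
        ti = simulate(dense_body, air, linear_closure_ut038,
                      FrameSpec("inertial"), BodyState.at_rest(), (0, 1.0),
                      t_eval=np.linspace(0, 1, 11))
        tt = simulate(dense_body, air, linear_closure_ut038,
                      FrameSpec("tunnel"), BodyState.at_rest(), (0, 1.0),
                      t_eval=np.linspace(0, 1, 21))
        with pytest.raises(ValueError):
            equivalence_deviation(ti, tt, None)
        with pytest.raises(ValueError):
            equivalence_deviation(tt, ti, None)


class TestTrajectoryContainer:
    def test_quaternion_stays_normalised(self, bottom_heavy_body, air):
        gust = GustProfile.sine(0.4, 6.0)
        closure = calibrate_closure_to_terminal_velocity(
            0.38, bottom_heavy_body, air, "quadratic", c_omega=1e-10)
        traj = simulate(bottom_heavy_body, air, closure,
                        FrameSpec("tunnel", gust, inflow=0.38 * X_UP),
                        BodyState.at_rest(), (0.0, 2.0),
                        t_eval=np.linspace(0, 2, 101))
        norms = np.linalg.norm(traj.quaternion, axis=1)
        assert norms == pytest.approx(np.ones_like(norms), abs=1e-12)

    def test_csv_round_trip(self, dense_body, air, tmp_path):
        import pandas as pd
        traj = simulate(dense_body, air, ZeroClosure(), FrameSpec("tunnel"),
                        BodyState.at_rest(), (0.0, 0.5),
                        t_eval=np.linspace(0, 0.5, 11))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[:8]) == ["t", "x", "y", "z", "u", "v", "w", "qw"]
        assert df["x"].to_numpy() == pytest.approx(traj.position[:, 0])
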