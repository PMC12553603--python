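"""Rigid-body free-fall dynamics in the inertial or the tunnel frame.

The same physical situation — a body settling in a vertical airstream
while the far-field air accelerates horizontally — can be integrated in
two frames:

* **inertial** (Earth-fixed): the ambient fluid moves at
  ``inflow + u_G(t)``; the gust contributes a uniform pressure-gradient
  force ``+rho_f V du_G/dt`` on the displaced volume, at the centre of
  buoyancy.
* **tunnel** (translating with the fluid, zero angular velocity): the
  ambient flow is unchanged (``inflow`` only); the gust appears as the
  fictitious body force ``-m du_G/dt`` at the centre of gravity plus the
  same pressure-gradient force — together the *reduced* gust force
  ``-m (1 - rho_f/rho_b) du_G/dt`` and a buoyancy torque in the effective
  gravity ``g - du_G/dt``.

The two descriptions are exactly equivalent; :func:`equivalence_deviation`
measures the residual left by the integrator after mapping one trajectory
into the other frame.

All buoyancy-type forces act at the centre of buoyancy, displaced
``e r_hat`` (body frame) from the centre of gravity; gravity and the
fictitious force act at the centre of gravity.  Orientation is carried as
a unit quaternion (scalar first), angular velocity in the body frame.

Coordinate convention: ``x`` vertical up (streamwise in the tunnel),
``y`` horizontal along the gust, ``z`` completing the right-handed triad
(into the viewing plane).  A positive rotation angle about ``z`` is a
clockwise tilt of the body top towards ``+y`` as seen by the camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .bodies_aero import AeroClosure, BodySpec
from .gusts import GustProfile
from .scales import FluidMedium, X_UP

__all__ = [
    "BodyState",
    "FrameSpec",
    "Trajectory",
    "transform_kinematics",
    "rhs_tunnel_frame",
    "rhs_inertial_frame",
    "integrate",
    "simulate",
    "equivalence_deviation",
    "hover_state",
    "StiffnessError",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: Step-wise error control runs this far below the requested tolerance so
#: the accumulated (global) error stays within the advertised one.
_STEP_SAFETY = 0.1


class StiffnessError(RuntimeError):
    """The adaptive integrator failed (step-size underflow or divergence)."""


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention, body -> frame)

def _quat_normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q)


def _quat_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _quat_derivative(q: np.ndarray, omega_body: np.ndarray) -> np.ndarray:
    """dq/dt = 1/2 q * (0, omega_body)."""
    w, x, y, z = q
    ox, oy, oz = omega_body
    return 0.5 * np.array([
        -x * ox - y * oy - z * oz,
        w * ox + y * oz - z * oy,
        w * oy - x * oz + z * ox,
        w * oz + x * oy - y * ox,
    ])


# ---------------------------------------------------------------------------
# state containers

@dataclass(frozen=True)
class BodyState:
    """Instantaneous rigid-body state in a stated frame."""

    position: np.ndarray       #: m
    velocity: np.ndarray       #: m/s
    quaternion: np.ndarray     #: unit, scalar-first, body -> frame
    omega_body: np.ndarray     #: rad/s, body frame
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("position", "velocity", "omega_body"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        q = np.asarray(self.quaternion, dtype=float)
        if q.shape != (4,):
            raise ValueError("quaternion must have 4 components")
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("quaternion must be unit norm")
        object.__setattr__(self, "quaternion", q / n)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.position, self.velocity,
                               self.quaternion, self.omega_body])

    @classmethod
    def unpack(cls, y: np.ndarray, t: float = 0.0) -> "BodyState":
        return cls(position=y[0:3], velocity=y[3:6],
                   quaternion=_quat_normalize(y[6:10]),
                   omega_body=y[10:13], t=t)

    @classmethod
    def at_rest(cls, position: Sequence[float] = (0.0, 0.0, 0.0),
                t: float = 0.0) -> "BodyState":
        return cls(position=np.asarray(position, float), velocity=np.zeros(3),
                   quaternion=np.array([1.0, 0.0, 0.0, 0.0]),
                   omega_body=np.zeros(3), t=t)

    def tilted(self, angle: float) -> "BodyState":
        """Same state, rotated by ``angle`` (rad, clockwise positive) about z."""
        half = 0.5 * angle
        q = np.array([np.cos(half), 0.0, 0.0, np.sin(half)])
        return BodyState(self.position, self.velocity, q, self.omega_body, self.t)


def hover_state(position: Sequence[float] = (0.0, 0.0, 0.0)) -> BodyState:
    """Upright body at rest in the tunnel frame (hover in the airstream)."""
    return BodyState.at_rest(position)


@dataclass(frozen=True)
class FrameSpec:
    """Which frame the equations are written in, plus the ambient flow.

    ``inflow`` is the steady tunnel airstream (vertical, tunnel frame);
    ``gust`` is the horizontal far-field motion.  The tunnel frame has
    zero angular velocity by construction, so no Coriolis, Euler or
    centripetal terms arise.
    """

    tag: str
    gust: GustProfile | None = None
    inflow: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.tag not in ("inertial", "tunnel"):
            raise ValueError("frame tag must be 'inertial' or 'tunnel'")
        v = np.asarray(self.inflow, dtype=float)
        if v.shape != (3,):
            raise ValueError("inflow must be a 3-vector")
        object.__setattr__(self, "inflow", v)


@dataclass
class Trajectory:
    """Time-ordered rigid-body states tagged with their frame."""

    t: np.ndarray              #: (n,)
    position: np.ndarray       #: (n, 3)
    velocity: np.ndarray       #: (n, 3)
    quaternion: np.ndarray     #: (n, 4)
    omega_body: np.ndarray     #: (n, 3)
    frame: str = "tunnel"
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> BodyState:
        return BodyState(self.position[i], self.velocity[i],
                         self.quaternion[i], self.omega_body[i],
                         t=float(self.t[i]))

    def tilt_angle(self) -> np.ndarray:
        """Stem angle theta(t), rad, positive clockwise (top towards +y).

        Angle of the body "up" axis (body x) from the vertical, projected
        on the x-y plane.
        """
        theta = np.empty(len(self.t))
        for i, q in enumerate(self.quaternion):
            up = _quat_matrix(_quat_normalize(q)) @ X_UP
            theta[i] = np.arctan2(up[1], up[0])
        return theta

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "t": self.t,
            "x": self.position[:, 0], "y": self.position[:, 1],
            "z": self.position[:, 2],
            "u": self.velocity[:, 0], "v": self.velocity[:, 1],
            "w": self.velocity[:, 2],
            "qw": self.quaternion[:, 0], "qx": self.quaternion[:, 1],
            "qy": self.quaternion[:, 2], "qz": self.quaternion[:, 3],
            "wx": self.omega_body[:, 0], "wy": self.omega_body[:, 1],
            "wz": self.omega_body[:, 2],
        }
        df = pd.DataFrame(cols)
        if self.diagnostics is not None:
            df = pd.concat([df, self.diagnostics.reset_index(drop=True)], axis=1)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# frame transforms

def transform_kinematics(x_prime, u_prime, a_prime, u_G, omega_G,
                         a_G, omega_dot_G):
    """Map a state from a moving frame to the inertial frame.

    Implements the general non-inertial kinematic relations

    ``u = u_G + u' + omega_G x x'``

    ``a = a_G + a' + 2 omega_G x u' + omega_dot_G x x'
    + omega_G x (omega_G x x')``

    i.e. frame translation plus, for a rotating frame, the Coriolis,
    Euler and centripetal accelerations.  The tunnel frame of this
    package has ``omega_G = 0``, collapsing to pure translation.
    """
    x_prime = np.asarray(x_prime, float)
    u_prime = np.asarray(u_prime, float)
    a_prime = np.asarray(a_prime, float)
    u_G = np.asarray(u_G, float)
    omega_G = np.asarray(omega_G, float)
    a_G = np.asarray(a_G, float)
    omega_dot_G = np.asarray(omega_dot_G, float)
    u = u_G + u_prime + np.cross(omega_G, x_prime)
    a = (a_G + a_prime + 2.0 * np.cross(omega_G, u_prime)
         + np.cross(omega_dot_G, x_prime)
         + np.cross(omega_G, np.cross(omega_G, x_prime)))
    return u, a


# ---------------------------------------------------------------------------
# right-hand sides

def _loads(t, y, body, medium, closure, u_fluid, a_G):
    """Common force/torque assembly given ambient fluid velocity and the
    gust acceleration of the far field (zero vector when no gust)."""
    vel = y[3:6]
    q = _quat_normalize(y[6:10])
    omega = y[10:13]
    R = _quat_matrix(q)

    u_rel = vel - u_fluid
    F_aero, T_aero_body = closure.evaluate(u_rel, R, omega, medium, body)

    g_vec = medium.gravity
    V = body.volume
    g_eff = g_vec - a_G                       # effective gravity
    F_buoy = -medium.density * V * g_eff      # at centre of buoyancy
    r_world = R @ (body.eccentricity * body.r_hat)
    T_buoy_world = np.cross(r_world, F_buoy)

    return q, omega, R, F_aero, T_aero_body, F_buoy, T_buoy_world, g_vec


def _angular_acceleration(body, omega, torque_body):
    return body.inertia_inv @ (torque_body - np.cross(omega, body.inertia @ omega))


def rhs_tunnel_frame(t: float, y: np.ndarray, body: BodySpec,
                     medium: FluidMedium, closure: AeroClosure,
                     gust: GustProfile | None,
                     inflow: np.ndarray) -> np.ndarray:
    """State derivative in the tunnel (gust-translating) frame.

    Linear momentum:
    ``m du'/dt = F + m g* g_hat - m (1 - rho_f/rho_b) du_G/dt``;
    angular momentum about the centre of gravity with the buoyancy force
    ``-rho_f V (g - du_G/dt)`` applied at the centre of buoyancy.
    """
    a_G = gust.acceleration_at(t) if gust is not None else np.zeros(3)
    (q, omega, R, F_aero, T_aero_body, F_buoy, T_buoy_world,
     g_vec) = _loads(t, y, body, medium, closure, inflow, a_G)
    # gravity + fictitious force at the centre of gravity
    F_cg = body.mass * (g_vec - a_G)
    lin_acc = (F_aero + F_cg + F_buoy) / body.mass
    torque_body = T_aero_body + R.T @ T_buoy_world
    ang_acc = _angular_acceleration(body, omega, torque_body)
    return np.concatenate([y[3:6], lin_acc, _quat_derivative(q, omega), ang_acc])


def rhs_inertial_frame(t: float, y: np.ndarray, body: BodySpec,
                       medium: FluidMedium, closure: AeroClosure,
                       gust: GustProfile | None,
                       inflow: np.ndarray) -> np.ndarray:
    """State derivative in the Earth-fixed frame.

    The ambient fluid moves at ``inflow + u_G(t)``; the gust's uniform
    pressure gradient exerts ``+rho_f V du_G/dt`` on the displaced volume
    at the centre of buoyancy.
    """
    if gust is not None:
        u_fluid = inflow + gust.velocity_at(t)
        a_G = gust.acceleration_at(t)
    else:
        u_fluid = inflow
        a_G = np.zeros(3)
    (q, omega, R, F_aero, T_aero_body, F_buoy, T_buoy_world,
     g_vec) = _loads(t, y, body, medium, closure, u_fluid, a_G)
    F_cg = body.mass * g_vec
    lin_acc = (F_aero + F_cg + F_buoy) / body.mass
    torque_body = T_aero_body + R.T @ T_buoy_world
    ang_acc = _angular_acceleration(body, omega, torque_body)
    return np.concatenate([y[3:6], lin_acc, _quat_derivative(q, omega), ang_acc])


# ---------------------------------------------------------------------------
# integration

def _apply_impulse(y: np.ndarray, dv_vec: np.ndarray, frame_tag: str,
                   body: BodySpec, medium: FluidMedium) -> np.ndarray:
    """Exact state jump across a step change ``dv_vec`` of the far field.

    The gust pressure impulse ``rho_f V dv`` kicks the body at the centre
    of buoyancy; in the tunnel frame the frame velocity itself also jumps.
    Body velocity jump: ``+ (rho_f/rho_b) dv`` (inertial) or
    ``- (1 - rho_f/rho_b) dv`` (tunnel).  Angular momentum jump:
    ``e r_world x (rho_f V dv)`` in either frame.
    """
    y = y.copy()
    rho = medium.density / body.mean_density
    if frame_tag == "tunnel":
        y[3:6] += -(1.0 - rho) * dv_vec
    else:
        y[3:6] += rho * dv_vec
    q = _quat_normalize(y[6:10])
    R = _quat_matrix(q)
    r_world = R @ (body.eccentricity * body.r_hat)
    dL_world = np.cross(r_world, medium.density * body.volume * dv_vec)
    y[10:13] += body.inertia_inv @ (R.T @ dL_world)
    return y


def integrate(rhs: Callable, state0: BodyState, t_span: tuple[float, float],
              t_eval: np.ndarray | None = None,
              breakpoints: Sequence[float] = (),
              impulses: Sequence[tuple[float, np.ndarray]] = (),
              impulse_apply: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
              frame: str = "tunnel") -> Trajectory:
    """Adaptive Runge-Kutta (4/5) integration with exact impulse handling.

    The interval is split at every breakpoint and impulse time so the
    integrator never steps across a derivative discontinuity; at impulse
    times the state jump is applied analytically via ``impulse_apply``.
    The quaternion is renormalised at every output sample.

    ``rtol``/``atol`` are targets for the *solution* error, not just the
    per-step error estimate: because step-wise control under-estimates the
    accumulated global error, the step controller runs a factor
    ``_STEP_SAFETY`` below the requested tolerances.
    """
    t0, t1 = t_span
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    if t_eval is None:
        t_eval = np.linspace(t0, t1, 501)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] < t0 or t_eval[-1] > t1:
        raise ValueError("t_eval must lie within t_span")

    imp = sorted((float(ti), np.asarray(dv, float)) for ti, dv in impulses
                 if t0 < ti < t1)
    cuts = sorted({float(b) for b in breakpoints if t0 < b < t1}
                  | {ti for ti, _ in imp})
    edges = [t0, *cuts, t1]
    imp_at = {ti: dv for ti, dv in imp}

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = state0.pack()
    for a, b in zip(edges[:-1], edges[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        # always include segment ends so the state chains across segments
        sol = solve_ivp(rhs, (a, b), y, method="RK45",
                        rtol=_STEP_SAFETY * rtol, atol=_STEP_SAFETY * atol,
                        t_eval=np.unique(np.concatenate([seg_eval, [a, b]])),
                        dense_output=False)
        if not sol.success:
            raise StiffnessError(
                f"integration failed in [{a}, {b}]: {sol.message}; "
                f"last state {y}")
        keep = np.isin(sol.t, seg_eval)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])
        y = sol.y[:, -1].copy()
        y[6:10] = _quat_normalize(y[6:10])
        if b in imp_at and impulse_apply is not None:
            y = impulse_apply(y, imp_at[b])

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # drop duplicated samples at segment joins, keeping the later segment's
    # value: outputs at an impulse time report the post-jump state, matching
    # the right-continuity convention of step profiles
    _, last_rev = np.unique(t_all[::-1], return_index=True)
    keep_idx = np.sort(t_all.size - 1 - last_rev)
    t_all = t_all[keep_idx]
    y_all = y_all[:, keep_idx]
    y_all[6:10] /= np.linalg.norm(y_all[6:10], axis=0)
    return Trajectory(t=t_all, position=y_all[0:3].T, velocity=y_all[3:6].T,
                      quaternion=y_all[6:10].T, omega_body=y_all[10:13].T,
                      frame=frame)


def simulate(body: BodySpec, medium: FluidMedium, closure: AeroClosure,
             frame: FrameSpec, state0: BodyState,
             t_span: tuple[float, float],
             t_eval: np.ndarray | None = None,
             rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
             diagnostics: bool = False) -> Trajectory:
    """Integrate the rigid-body equations in the requested frame.

    At exact neutral buoyancy (``rho_f == rho_b``) with a concentric body
    (``e == 0``) the gust terms of the tunnel-frame equations vanish
    identically, so the gust is dropped from the event list and the run
    is bit-identical to the ungusted one — the null-response property of
    the accelerating-frame method.
    """
    gust = frame.gust
    if (frame.tag == "tunnel" and gust is not None
            and medium.density == body.mean_density
            and body.eccentricity == 0.0):
        gust = None

    if frame.tag == "tunnel":
        def rhs(t, y):
            return rhs_tunnel_frame(t, y, body, medium, closure, gust,
                                    frame.inflow)
    else:
        def rhs(t, y):
            return rhs_inertial_frame(t, y, body, medium, closure, gust,
                                      frame.inflow)

    if gust is not None:
        breakpoints = gust.breakpoints()
        impulses = [(i.t, i.dv * gust.direction) for i in gust.impulses]
    else:
        breakpoints, impulses = (), []

    def apply(y, dv_vec):
        return _apply_impulse(y, dv_vec, frame.tag, body, medium)

    traj = integrate(rhs, state0, t_span, t_eval=t_eval,
                     breakpoints=breakpoints, impulses=impulses,
                     impulse_apply=apply, rtol=rtol, atol=atol,
                     frame=frame.tag)
    if diagnostics:
        traj.diagnostics = _diagnostics(traj, body, medium, closure, frame, gust)
    return traj


def _diagnostics(traj: Trajectory, body, medium, closure, frame,
                 gust) -> pd.DataFrame:
    """Per-sample force/torque component breakdown (world frame)."""
    rows = []
    for i, t in enumerate(traj.t):
        y = np.concatenate([traj.position[i], traj.velocity[i],
                            traj.quaternion[i], traj.omega_body[i]])
        if frame.tag == "tunnel":
            u_fluid = frame.inflow
            a_G = gust.acceleration_at(t) if gust is not None else np.zeros(3)
            F_fict = -body.mass * a_G
        else:
            if gust is not None:
                u_fluid = frame.inflow + gust.velocity_at(t)
                a_G = gust.acceleration_at(t)
            else:
                u_fluid = frame.inflow
                a_G = np.zeros(3)
            F_fict = np.zeros(3)
        (_, _, _, F_aero, T_aero_body, F_buoy, T_buoy_world,
         g_vec) = _loads(t, y, body, medium, closure, u_fluid, a_G)
        rows.append({
            "F_aero_x": F_aero[0], "F_aero_y": F_aero[1], "F_aero_z": F_aero[2],
            "F_gravity_x": body.mass * g_vec[0],
            "F_gravity_y": body.mass * g_vec[1],
            "F_gravity_z": body.mass * g_vec[2],
            "F_buoyancy_x": F_buoy[0], "F_buoyancy_y": F_buoy[1],
            "F_buoyancy_z": F_buoy[2],
            "F_fictitious_x": F_fict[0], "F_fictitious_y": F_fict[1],
            "F_fictitious_z": F_fict[2],
            "T_aero_body_z": T_aero_body[2],
            "T_buoyancy_z": T_buoy_world[2],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frame-equivalence check

def equivalence_deviation(traj_inertial: Trajectory, traj_tunnel: Trajectory,
                          gust: GustProfile | None) -> tuple[float, float]:
    """Max position/velocity mismatch after mapping frames onto each other.

    The inertial trajectory is mapped into the tunnel frame by
    subtracting the frame displacement ``integral u_G dt`` and velocity
    ``u_G(t)``; the result is compared sample-by-sample with the
    tunnel-frame trajectory.  Both runs must share the body, closure,
    initial relative state and the output time grid.
    """
    if traj_inertial.frame != "inertial" or traj_tunnel.frame != "tunnel":
        raise ValueError("pass (inertial, tunnel) trajectories in that order")
    if len(traj_inertial) != len(traj_tunnel) or not np.allclose(
            traj_inertial.t, traj_tunnel.t, rtol=0, atol=1e-12):
        raise ValueError("trajectories must share the output time grid")
    t = traj_inertial.t
    if gust is not None:
        disp = np.outer(gust.displacement_at(t), gust.direction)
        vel = np.outer(gust.speed_at(t), gust.direction)
    else:
        disp = np.zeros((len(t), 3))
        vel = np.zeros((len(t), 3))
    dx = traj_inertial.position - disp - traj_tunnel.position
    du = traj_inertial.velocity - vel - traj_tunnel.velocity
    return (float(np.max(np.linalg.norm(dx, axis=1))),
            float(np.max(np.linalg.norm(du, axis=1))))
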