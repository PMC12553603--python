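"""Gust profiles, the reduced gust acceleration and effective gravity.

A uniform irrotational transverse gust is modelled as a rigid horizontal
acceleration of the far-field fluid, ``u_G(t)``.  In a frame translating
with the fluid the gust acts on an immersed body purely as a body force
``-m (1 - rho_f/rho_b) du_G/dt`` (the gust acceleration net of its own
buoyancy), equivalently as a temporary tilt and rescaling of gravity:
``g_eff = g - du_G/dt``.

Profiles are total functions of time.  A *step* profile carries its jump
as an explicit impulse record instead of a Dirac spike so integrators can
apply the corresponding velocity change exactly; this preserves the exact
cancellation of the gust response at neutral buoyancy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .scales import X_UP

__all__ = [
    "GustProfile",
    "GustImpulse",
    "EffectiveGravity",
    "reduced_gust_acceleration",
    "effective_gravity",
    "gust_ratio",
    "Y_GUST",
]

#: Default (horizontal) gust direction, orthogonal to the vertical flight axis.
Y_GUST = np.array([0.0, 1.0, 0.0])

_KINDS = ("step", "ramp", "sine", "tabulated")


@dataclass(frozen=True)
class GustImpulse:
    """Instantaneous far-field velocity change ``dv`` (m/s, signed) at ``t``."""

    t: float
    dv: float


@dataclass(frozen=True)
class GustProfile:
    """Far-field gust velocity ``u_G(t)`` along a fixed horizontal direction.

    Construct via the classmethods :meth:`step`, :meth:`ramp`, :meth:`sine`
    or :meth:`tabulated` rather than directly.  ``speed_at``/``accel_at``
    give the signed scalar along ``direction``; ``velocity_at`` and
    ``acceleration_at`` give the 3-vectors.
    """

    kind: str
    direction: np.ndarray = field(default_factory=lambda: Y_GUST.copy())
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown gust kind {self.kind!r}")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            raise ValueError("gust direction must be a unit vector")
        if abs(d[0]) > 1e-12:
            warnings.warn(
                "gust direction is not orthogonal to the vertical flight "
                "axis; proceeding, but this is not a transverse gust",
                stacklevel=2,
            )
        object.__setattr__(self, "direction", d)

    # -- constructors ------------------------------------------------------

    @classmethod
    def step(cls, v1: float, t0: float = 0.0,
             direction: np.ndarray = Y_GUST) -> "GustProfile":
        """Step from 0 to ``v1`` at ``t0`` (right-continuous at ``t0``)."""
        return cls("step", np.asarray(direction, float), {"v1": float(v1), "t0": float(t0)})

    @classmethod
    def ramp(cls, t0: float, dt: float, dv: float, v0: float = 0.0,
             direction: np.ndarray = Y_GUST) -> "GustProfile":
        """Linear change by ``dv`` over ``[t0, t0+dt]`` from plateau ``v0``."""
        if dt <= 0:
            raise ValueError("ramp duration must be positive")
        return cls("ramp", np.asarray(direction, float),
                   {"t0": float(t0), "dt": float(dt), "dv": float(dv), "v0": float(v0)})

    @classmethod
    def sine(cls, amplitude: float, omega: float, phase: float = 0.0,
             direction: np.ndarray = Y_GUST) -> "GustProfile":
        """``u_G(t) = A sin(omega t + phase)``."""
        return cls("sine", np.asarray(direction, float),
                   {"A": float(amplitude), "omega": float(omega), "phase": float(phase)})

    @classmethod
    def tabulated(cls, times: np.ndarray, speeds: np.ndarray,
                  direction: np.ndarray = Y_GUST) -> "GustProfile":
        """Sampled profile; linear interpolation, constant extrapolation."""
        t = np.asarray(times, dtype=float)
        v = np.asarray(speeds, dtype=float)
        if t.ndim != 1 or t.size < 2 or t.shape != v.shape:
            raise ValueError("tabulated profile needs matching 1-d time/speed grids")
        if np.any(np.diff(t) <= 0):
            raise ValueError("tabulated time grid must be strictly increasing")
        # precompute second-order centred finite-difference acceleration
        a = np.gradient(v, t, edge_order=2 if t.size > 2 else 1)
        return cls("tabulated", np.asarray(direction, float),
                   {"t": t, "v": v, "a": a})

    # -- scalar evaluation -------------------------------------------------

    def speed_at(self, t):
        """Signed gust speed along ``direction`` at time(s) ``t``."""
        p = self.params
        t = np.asarray(t, dtype=float)
        if self.kind == "step":
            out = np.where(t >= p["t0"], p["v1"], 0.0)
        elif self.kind == "ramp":
            s = np.clip((t - p["t0"]) / p["dt"], 0.0, 1.0)
            out = p["v0"] + p["dv"] * s
        elif self.kind == "sine":
            out = p["A"] * np.sin(p["omega"] * t + p["phase"])
        else:
            out = np.interp(t, p["t"], p["v"])
        return out if out.ndim else float(out)

    def accel_at(self, t):
        """Signed gust acceleration along ``direction``.

        For step profiles this is zero everywhere; the jump is carried by
        :attr:`impulses`.  Tabulated profiles use the centred second-order
        finite difference of their samples.
        """
        p = self.params
        t = np.asarray(t, dtype=float)
        if self.kind == "step":
            out = np.zeros_like(t)
        elif self.kind == "ramp":
            inside = (t >= p["t0"]) & (t < p["t0"] + p["dt"])
            out = np.where(inside, p["dv"] / p["dt"], 0.0)
        elif self.kind == "sine":
            out = p["A"] * p["omega"] * np.cos(p["omega"] * t + p["phase"])
        else:
            out = np.interp(t, p["t"], p["a"])
        return out if out.ndim else float(out)

    def displacement_at(self, t):
        """Frame displacement ``integral_0^t u_G ds`` along ``direction``."""
        t = np.asarray(t, dtype=float)
        out = self._antiderivative(t) - self._antiderivative(np.asarray(0.0))
        return out if out.ndim else float(out)

    def _antiderivative(self, t: np.ndarray) -> np.ndarray:
        p = self.params
        if self.kind == "step":
            return p["v1"] * np.maximum(t - p["t0"], 0.0)
        if self.kind == "ramp":
            t0, dt, dv, v0 = p["t0"], p["dt"], p["dv"], p["v0"]
            s = np.clip(t - t0, 0.0, dt)
            after = np.maximum(t - t0 - dt, 0.0)
            return v0 * t + dv * (s * s / (2.0 * dt) + after)
        if self.kind == "sine":
            A, w, ph = p["A"], p["omega"], p["phase"]
            return -A / w * np.cos(w * t + ph)
        tt, vv = p["t"], p["v"]
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (vv[1:] + vv[:-1]) * np.diff(tt))])
        # piecewise-linear speed: trapezoid cumulative is exact at nodes,
        # linear interpolation between nodes is O(dt^2); constant-speed
        # extrapolation outside the grid
        return np.where(
            t <= tt[0],
            vv[0] * (t - tt[0]),
            np.where(t >= tt[-1],
                     cum[-1] + vv[-1] * (t - tt[-1]),
                     np.interp(t, tt, cum)),
        )

    # -- vector evaluation -------------------------------------------------

    def velocity_at(self, t: float) -> np.ndarray:
        return self.speed_at(t) * self.direction

    def acceleration_at(self, t: float) -> np.ndarray:
        return self.accel_at(t) * self.direction

    # -- event structure ---------------------------------------------------

    @property
    def impulses(self) -> tuple[GustImpulse, ...]:
        """Velocity jumps to be applied analytically by an integrator."""
        if self.kind == "step":
            return (GustImpulse(self.params["t0"], self.params["v1"]),)
        return ()

    def breakpoints(self) -> tuple[float, ...]:
        """Times where the profile is not smooth (integration restarts)."""
        p = self.params
        if self.kind == "step":
            return (p["t0"],)
        if self.kind == "ramp":
            return (p["t0"], p["t0"] + p["dt"])
        if self.kind == "tabulated":
            return (float(p["t"][0]), float(p["t"][-1]))
        return ()


@dataclass(frozen=True)
class EffectiveGravity:
    """Gravity as perceived during a gust: ``g_eff = g - du_G/dt``."""

    vector: np.ndarray
    magnitude: float
    tilt: float  #: angle (rad) between g_eff and g, away from the gust direction

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", v)
        if abs(self.magnitude - np.linalg.norm(v)) > 1e-12 * max(1.0, self.magnitude):
            raise ValueError("magnitude inconsistent with vector")


def reduced_gust_acceleration(a_G, rho_f: float, rho_b: float):
    """Gust acceleration net of its specific buoyancy force.

    ``(1 - rho_f/rho_b) * a_G``, componentwise for vectors.  This is the
    body force per unit mass felt in the tunnel frame; it vanishes
    identically at neutral buoyancy.
    """
    if rho_f <= 0 or rho_b <= 0:
        raise ValueError("densities must be positive")
    return (1.0 - rho_f / rho_b) * np.asarray(a_G, dtype=float)


def effective_gravity(g_vec: np.ndarray, a_G_vec: np.ndarray) -> EffectiveGravity:
    """Effective gravity ``g - a_G`` with magnitude and tilt from ``g``.

    For a horizontal gust (``a_G`` orthogonal to ``g``) the magnitude is
    ``sqrt(g^2 + a_G^2)`` and the tilt is ``arctan(a_G/g)`` away from the
    gust direction.
    """
    g = np.asarray(g_vec, dtype=float)
    a = np.asarray(a_G_vec, dtype=float)
    gn = np.linalg.norm(g)
    if gn == 0:
        raise ValueError("gravity vector must be non-zero")
    v = g - a
    mag = float(np.linalg.norm(v))
    tilt = float(math.atan2(np.linalg.norm(np.cross(g, v)), float(np.dot(g, v))))
    return EffectiveGravity(vector=v, magnitude=mag, tilt=tilt)


def gust_ratio(u_gust_max: float, u_flyer: float) -> float:
    """``G_R``: peak gust speed over the flyer's characteristic speed."""
    if u_flyer <= 0:
        raise ValueError("flyer speed must be positive")
    return abs(u_gust_max) / u_flyer
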