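"""Body specification and pluggable quasi-steady aerodynamic closures.

The rigid-body equations need the fluid force ``F`` and torque ``T_o``
about the centre of gravity.  In the accelerating-tunnel method these are
whatever the real flow (or a CFD solver) provides; here they are supplied
by explicit quasi-steady closures so the dynamics can be exercised and
checked against closed forms.  The two built-in closures — linear drag
(an analytic oracle) and quadratic drag (diaspore-like) — are stand-ins:
the :class:`AeroClosure` interface is the documented extension point for
measured or computed loads.

Buoyancy-type forces, which act at the centre of buoyancy, are *not* part
of a closure; :mod:`gustfall.dynamics` applies them, keeping the
decomposition "aerodynamic loads vs gravity/buoyancy" intact.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .scales import FluidMedium, reduced_gravity, X_UP

__all__ = [
    "BodySpec",
    "AeroClosure",
    "LinearDragClosure",
    "QuadraticDragClosure",
    "ZeroClosure",
    "linear_drag_closure",
    "quadratic_drag_closure",
    "terminal_velocity",
    "calibrate_closure_to_terminal_velocity",
    "ClosureInconsistencyError",
]


class ClosureInconsistencyError(RuntimeError):
    """No terminal-velocity bracket found for the given closure/body pair."""


@dataclass(frozen=True)
class BodySpec:
    """Rigid body: mass, mean density, inertia and buoyancy-centre offset.

    Parameters
    ----------
    mass : float
        Body mass in kg.
    mean_density : float
        Mean density ``rho_b = mass / displaced volume`` in kg m^-3.
    length : float
        Reference length (e.g. pappus diameter) in m.
    inertia : ndarray, shape (3, 3)
        Inertia tensor about the centre of gravity, body frame, kg m^2.
        Symmetric positive definite.  A 3-vector is accepted as a diagonal.
    eccentricity : float
        Distance ``e >= 0`` (m) from centre of gravity to centre of
        buoyancy.
    r_hat : ndarray, shape (3,)
        Unit vector, body frame, from the centre of gravity to the centre
        of buoyancy.  ``+x`` (body "up") for a bottom-heavy flyer such as
        a dandelion diaspore, whose seed sits below the pappus.
    """

    mass: float
    mean_density: float
    length: float
    inertia: np.ndarray
    eccentricity: float = 0.0
    r_hat: np.ndarray = field(default_factory=lambda: X_UP.copy())

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.length <= 0 or self.mean_density <= 0:
            raise ValueError("mass, mean_density and length must be positive")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be non-negative")
        inertia = np.asarray(self.inertia, dtype=float)
        if inertia.shape == (3,):
            inertia = np.diag(inertia)
        if inertia.shape != (3, 3):
            raise ValueError("inertia must be a 3x3 tensor or a 3-vector diagonal")
        if not np.allclose(inertia, inertia.T, rtol=1e-10, atol=0):
            raise ValueError("inertia tensor must be symmetric")
        if np.any(np.linalg.eigvalsh(inertia) <= 0):
            raise ValueError("inertia tensor must be positive definite")
        r = np.asarray(self.r_hat, dtype=float)
        if abs(np.linalg.norm(r) - 1.0) > 1e-12:
            raise ValueError("r_hat must be a unit vector")
        object.__setattr__(self, "inertia", inertia)
        object.__setattr__(self, "r_hat", r)
        object.__setattr__(self, "_inertia_inv", np.linalg.inv(inertia))

    @property
    def volume(self) -> float:
        """Displaced volume ``m / rho_b`` in m^3."""
        return self.mass / self.mean_density

    @property
    def inertia_inv(self) -> np.ndarray:
        return self._inertia_inv

    def reduced_gravity_in(self, medium: FluidMedium) -> float:
        return reduced_gravity(medium.g_magnitude, medium.density,
                               self.mean_density)


class AeroClosure(ABC):
    """Quasi-steady load model: relative velocity and spin in, loads out.

    Contract: zero relative velocity and zero angular velocity give
    exactly zero force and torque, and both outputs are continuous in
    their arguments.  The force is returned in the integration frame; the
    torque about the centre of gravity in the body frame.
    """

    @abstractmethod
    def evaluate(self, u_rel: np.ndarray, rotation: np.ndarray,
                 omega_body: np.ndarray, medium: FluidMedium,
                 body: BodySpec) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(force, torque_body)`` in N and N m.

        Parameters
        ----------
        u_rel : velocity of the body relative to the ambient fluid at the
            body location, integration frame, m/s.
        rotation : 3x3 body-to-frame rotation matrix.
        omega_body : body-frame angular velocity, rad/s.
        """


@dataclass(frozen=True)
class ZeroClosure(AeroClosure):
    """Vacuum closure: no aerodynamic loads (ballistic oracle runs)."""

    def evaluate(self, u_rel, rotation, omega_body, medium, body):
        return np.zeros(3), np.zeros(3)


@dataclass(frozen=True)
class LinearDragClosure(AeroClosure):
    """Stokes-like isotropic drag ``F = -c u_rel`` with spin damping.

    The analytic oracle closure: terminal velocity ``u_t = m g*/c`` and
    exponential velocity relaxation with time constant ``tau = m/c`` in
    closed form.
    """

    c: float
    c_omega: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0 or self.c_omega < 0:
            raise ValueError("require c > 0 and c_omega >= 0")

    def evaluate(self, u_rel, rotation, omega_body, medium, body):
        return -self.c * np.asarray(u_rel, float), -self.c_omega * np.asarray(omega_body, float)


@dataclass(frozen=True)
class QuadraticDragClosure(AeroClosure):
    """Bluff-body drag ``F = -1/2 rho_f C_D A |u_rel| u_rel`` with spin damping.

    The diaspore-like closure: drag grows with the *speed* of the relative
    motion, so a transverse slip increases the vertical drag component —
    the mechanism behind the transient altitude gain of a hovering body
    hit by a horizontal gust.
    """

    C_D: float
    area: float
    c_omega: float = 0.0

    def __post_init__(self) -> None:
        if self.C_D <= 0 or self.area <= 0 or self.c_omega < 0:
            raise ValueError("require C_D > 0, area > 0 and c_omega >= 0")

    def evaluate(self, u_rel, rotation, omega_body, medium, body):
        u_rel = np.asarray(u_rel, float)
        force = -0.5 * medium.density * self.C_D * self.area \
            * np.linalg.norm(u_rel) * u_rel
        return force, -self.c_omega * np.asarray(omega_body, float)


def linear_drag_closure(c: float, c_omega: float = 0.0) -> LinearDragClosure:
    return LinearDragClosure(c=c, c_omega=c_omega)


def quadratic_drag_closure(C_D: float, area: float,
                           c_omega: float = 0.0) -> QuadraticDragClosure:
    return QuadraticDragClosure(C_D=C_D, area=area, c_omega=c_omega)


_IDENTITY = np.eye(3)
_ZERO3 = np.zeros(3)


def _vertical_drag(u: float, body: BodySpec, medium: FluidMedium,
                   closure: AeroClosure) -> float:
    """Upward drag component on a body falling at speed ``u``."""
    force, _ = closure.evaluate(-u * X_UP, _IDENTITY, _ZERO3, medium, body)
    return float(force @ X_UP)


def terminal_velocity(body: BodySpec, medium: FluidMedium,
                      closure: AeroClosure,
                      bracket: tuple[float, float] = (1e-6, 1e3)) -> float:
    """Steady settling speed: drag balances the reduced weight.

    Solved by bracketing root finding on the vertical force balance; for
    the built-in closures this agrees with the closed forms
    ``m g*/c`` (linear) and ``sqrt(2 m g*/(rho_f C_D A))`` (quadratic)
    to better than 1e-9 relative.

    Raises
    ------
    ValueError
        If the body is not falling (``g* <= 0``): no terminal fall exists
        at or below neutral buoyancy.
    ClosureInconsistencyError
        If no sign change of the force balance is found in ``bracket``.
    """
    g_star = body.reduced_gravity_in(medium)
    if g_star <= 0:
        raise ValueError("terminal fall requires g* > 0 (body denser than fluid)")
    weight = body.mass * g_star

    def residual(u: float) -> float:
        return _vertical_drag(u, body, medium, closure) - weight

    lo, hi = bracket
    if residual(lo) > 0 or residual(hi) < 0:
        raise ClosureInconsistencyError(
            "no terminal-velocity bracket in "
            f"[{lo}, {hi}] m/s for this closure/body pair")
    return float(brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16))


def calibrate_closure_to_terminal_velocity(
        u_t_target: float, body: BodySpec, medium: FluidMedium,
        family: str = "quadratic", c_omega: float = 0.0,
        area: float | None = None) -> AeroClosure:
    """Closed-form inverse: build a closure whose terminal velocity is given.

    ``family`` is ``"linear"`` (returns ``c = m g*/u_t``) or
    ``"quadratic"`` (returns ``C_D A = 2 m g*/(rho_f u_t^2)``; the split
    between ``C_D`` and ``area`` is irrelevant to the dynamics, so a
    reference ``area`` may be supplied for reporting, defaulting to the
    body's ``length``-diameter disc).
    """
    if u_t_target <= 0:
        raise ValueError("target terminal velocity must be positive")
    g_star = body.reduced_gravity_in(medium)
    if g_star <= 0:
        raise ValueError("calibration requires g* > 0 (falling body)")
    weight = body.mass * g_star
    if family == "linear":
        return LinearDragClosure(c=weight / u_t_target, c_omega=c_omega)
    if family == "quadratic":
        cda = 2.0 * weight / (medium.density * u_t_target**2)
        if area is None:
            area = np.pi * (body.length / 2.0) ** 2
        return QuadraticDragClosure(C_D=cda / area, area=area, c_omega=c_omega)
    raise ValueError(f"unknown closure family {family!r}")
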