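"""Dimensional scaling and the dimensionless groups of free fall.

A rigid body settling in a quiescent fluid is governed, once the equations
are made dimensionless with the fluid density :math:`\\hat\\rho_f`, a body
length :math:`\\hat l` and the gravitational velocity

.. math:: \\hat u_g \\equiv (\\hat m \\hat g^* / \\hat\\rho_f \\hat l^2)^{1/2},

by the Galilei number :math:`Ga = \\hat u_g \\hat l/\\hat\\nu` (the a-priori
control parameter of sedimentation problems) together with the density
ratio :math:`\\rho = \\hat\\rho_f/\\hat\\rho_b`.  Here :math:`\\hat g^*` is the
reduced gravitational acceleration, i.e. gravity net of the specific
buoyancy force, :math:`(1-\\hat\\rho_f/\\hat\\rho_b)\\hat g`.

All computation elsewhere in the package is carried out in dimensional SI
form; these groups are *derived* reporting quantities.  That choice keeps
the neutrally buoyant case :math:`\\rho = 1` representable (the scaling
velocity :math:`\\hat u_g` is singular there, the physics is not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidMedium",
    "ScaleSet",
    "NeutralBuoyancyError",
    "reduced_gravity",
    "gravitational_velocity",
    "galilei_number",
    "reynolds_number",
    "disc_geometry_factor",
    "scale_set",
]

#: Standard gravity magnitude, m s^-2.
STANDARD_GRAVITY = 9.81

#: Vertical-up unit vector of the tunnel convention (x up, y = gust axis).
X_UP = np.array([1.0, 0.0, 0.0])


class NeutralBuoyancyError(ValueError):
    """The gravitational-velocity scaling is singular at neutral buoyancy.

    ``u_g = sqrt(m g*/(rho_f l^2))`` requires ``g* != 0`` and therefore
    ``rho_f/rho_b != 1``.  Dimensional simulation of the neutrally buoyant
    case remains possible; only the dimensionless report is unavailable.
    """


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class FluidMedium:
    """Ambient fluid: density, kinematic viscosity and gravity vector.

    Parameters
    ----------
    density : float
        Fluid density ``rho_f`` in kg m^-3.
    kinematic_viscosity : float
        Kinematic viscosity ``nu`` in m^2 s^-1.
    gravity : ndarray, shape (3,)
        Gravity vector in m s^-2.  Default points "down" along ``-x`` in
        the tunnel convention (x vertical up), magnitude 9.81.
    """

    density: float
    kinematic_viscosity: float
    gravity: np.ndarray = field(
        default_factory=lambda: -STANDARD_GRAVITY * X_UP.copy()
    )

    def __post_init__(self) -> None:
        _check_positive(density=self.density,
                        kinematic_viscosity=self.kinematic_viscosity)
        g = np.asarray(self.gravity, dtype=float)
        if g.shape != (3,):
            raise ValueError("gravity must be a 3-vector")
        if not np.all(np.isfinite(g)) or np.linalg.norm(g) == 0:
            raise ValueError("gravity must be finite and non-zero")
        object.__setattr__(self, "gravity", g)

    @property
    def g_magnitude(self) -> float:
        return float(np.linalg.norm(self.gravity))


#: Dry air at roughly 20 C.
AIR = FluidMedium(density=1.2, kinematic_viscosity=1.5e-5)


@dataclass(frozen=True)
class ScaleSet:
    """Derived scales and dimensionless groups for one body/medium pair.

    Attributes
    ----------
    reduced_gravity : float
        ``g* = (1 - rho_f/rho_b) g`` in m s^-2 (signed; negative for a
        buoyant body).
    gravitational_velocity : float
        ``u_g = sqrt(m |g*| / (rho_f l^2))`` in m s^-1.
    galilei : float
        ``Ga = u_g l / nu``.
    density_ratio : float
        ``rho = rho_f / rho_b``.
    mass : float
        Dimensionless mass ``m / (rho_f l^3)``.
    geometry_factor : float
        ``chi = mass / density_ratio`` — purely geometric for a body of
        uniform density (``pi f / l`` for a disc of thickness ``f``).
    """

    reduced_gravity: float
    gravitational_velocity: float
    galilei: float
    density_ratio: float
    mass: float
    geometry_factor: float

    def as_dict(self) -> dict[str, float]:
        return {
            "reduced_gravity_m_s2": self.reduced_gravity,
            "gravitational_velocity_m_s": self.gravitational_velocity,
            "galilei": self.galilei,
            "density_ratio": self.density_ratio,
            "mass_nondim": self.mass,
            "geometry_factor": self.geometry_factor,
        }


def reduced_gravity(g_mag: float, rho_f: float, rho_b: float) -> float:
    """Gravity net of the specific buoyancy force, ``(1 - rho_f/rho_b) g``.

    Signed: zero at neutral buoyancy, negative for a body lighter than the
    fluid it displaces.
    """
    _check_positive(rho_f=rho_f, rho_b=rho_b)
    return (1.0 - rho_f / rho_b) * g_mag


def gravitational_velocity(m: float, g_star: float, rho_f: float, l: float) -> float:
    """Velocity scale ``sqrt(m |g*| / (rho_f l^2))`` of gravitational settling.

    Raises
    ------
    NeutralBuoyancyError
        If ``g_star`` is zero — the non-dimensionalisation requires
        ``u_g != 0`` and thus ``rho_f/rho_b != 1``.
    """
    _check_positive(m=m, rho_f=rho_f, l=l)
    if g_star == 0:
        raise NeutralBuoyancyError(
            "u_g is undefined at neutral buoyancy (g* = 0, rho_f/rho_b = 1)"
        )
    return math.sqrt(m * abs(g_star) / (rho_f * l * l))


def galilei_number(u_g: float, l: float, nu: float) -> float:
    """``Ga = u_g l / nu``: gravitational versus viscous forces."""
    _check_positive(u_g=u_g, l=l, nu=nu)
    return u_g * l / nu


def reynolds_number(u_t: float, l: float, nu: float) -> float:
    """``Re = u_t l / nu`` based on the terminal velocity.

    Unlike ``Ga``, ``Re`` is not known a priori: the terminal velocity is
    an outcome of the force balance.
    """
    _check_positive(u_t=u_t, l=l, nu=nu)
    return u_t * l / nu


def disc_geometry_factor(f: float, l: float) -> float:
    """Geometry factor ``chi = pi f / l`` of a disc of thickness ``f``."""
    _check_positive(f=f, l=l)
    return math.pi * f / l


def scale_set(mass: float, rho_b: float, length: float,
              medium: FluidMedium) -> ScaleSet:
    """Assemble the full scale report for a body in a medium.

    Raises :class:`NeutralBuoyancyError` when ``rho_f == rho_b``; callers
    that must handle the neutrally buoyant case (the simulator does) should
    catch it and omit the dimensionless block.
    """
    _check_positive(mass=mass, rho_b=rho_b, length=length)
    g_star = reduced_gravity(medium.g_magnitude, medium.density, rho_b)
    u_g = gravitational_velocity(mass, g_star, medium.density, length)
    rho = medium.density / rho_b
    m_nd = mass / (medium.density * length**3)
    return ScaleSet(
        reduced_gravity=g_star,
        gravitational_velocity=u_g,
        galilei=galilei_number(u_g, length, medium.kinematic_viscosity),
        density_ratio=rho,
        mass=m_nd,
        geometry_factor=m_nd / rho,
    )
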