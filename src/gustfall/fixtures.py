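"""Seeded synthetic data emulating the accelerating-tunnel facility.

Everything here is generated, never downloaded: gridded velocity-field
series with a prescribed turbulence intensity, pixel tracks of a marker
on the translating tunnel (750 fps, 0.0805 mm/px imaging), a virtual
dandelion-like diaspore with a calibrated terminal velocity of 0.38 m/s,
and the demonstration scenario — hover, then a horizontal translation at
twice the terminal velocity stopped by a smooth deceleration peaking at
11 m/s^2 (gust ratio 2).

Generators are pure functions of their parameters and seed: the same
seed gives byte-identical output.  The diaspore's unmeasured properties
(mass, inertia, buoyancy-centre offset, drag area) are plausible
order-of-magnitude choices, flagged ``assumed_defaults`` in the
metadata they carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma

from . import tracking
from .bodies_aero import (AeroClosure, BodySpec,
                          calibrate_closure_to_terminal_velocity)
from .dynamics import BodyState, FrameSpec, Trajectory, simulate
from .flow_analysis import VectorFieldSeries
from .gusts import GustProfile, gust_ratio
from .scales import AIR, FluidMedium, X_UP
from .tracking import TrackSeries

__all__ = [
    "FixtureSpec",
    "synth_field_series",
    "synth_tunnel_track",
    "virtual_diaspore",
    "VirtualDiaspore",
    "demo_gust_profile",
    "demo_scenario",
    "DemoScenario",
    "DemoResult",
    "DIASPORE_TERMINAL_VELOCITY",
]

#: Terminal velocity of the tested diaspore, m/s.
DIASPORE_TERMINAL_VELOCITY = 0.38

#: Demonstration gust: plateau speed (exactly -2 u_t), onset, stop, peak
#: deceleration of the smooth stopping profile.
DEMO_PLATEAU_SPEED = -2.0 * DIASPORE_TERMINAL_VELOCITY
DEMO_GUST_ONSET = 0.1          # s
DEMO_GUST_STOP = 0.27          # s
DEMO_PEAK_DECELERATION = 11.0  # m/s^2


@dataclass(frozen=True)
class FixtureSpec:
    """Bundle of defaults shared by the generators."""

    seed: int = 0
    frame_rate: float = tracking.FRAME_RATE_DEFAULT          # 750 fps
    resolution: float = tracking.MM_PER_PX_DEFAULT           # 0.0805 mm/px
    noise_px: float = 1.0
    grid_spacing: float = 2e-3                               # m
    window_height: float = 40e-3                             # m (x extent)
    window_width: float = 80e-3                              # m (y extent)
    n_frames: int = 2000
    intensity: float = 0.008
    mean_speed: float = DIASPORE_TERMINAL_VELOCITY

    def __post_init__(self) -> None:
        if self.noise_px < 0 or self.intensity < 0:
            raise ValueError("noise and intensity must be non-negative")


def synth_field_series(mean_speed: float, intensity: float,
                       x: np.ndarray | None = None,
                       y: np.ndarray | None = None,
                       n_frames: int = 2000, seed: int = 0,
                       frame_rate: float = tracking.FRAME_RATE_DEFAULT
                       ) -> VectorFieldSeries:
    """Uniform vertical mean flow plus isotropic Gaussian fluctuations.

    Fluctuations on both components have standard deviation
    ``intensity * mean_speed``, so the expected pointwise turbulence
    intensity (RMS of both components over two, divided by the local mean
    speed) equals ``intensity`` up to O(intensity^2) sampling bias.
    ``intensity = 0`` gives an exactly constant field.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    spec = FixtureSpec()
    if x is None:
        half = spec.window_height / 2
        x = np.arange(-half, half + spec.grid_spacing / 2, spec.grid_spacing)
    if y is None:
        half = spec.window_width / 2
        y = np.arange(-half, half + spec.grid_spacing / 2, spec.grid_spacing)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    shape = (n_frames, x.size, y.size)
    sigma = intensity * mean_speed
    if sigma == 0:
        du = np.zeros(shape)
        dv = np.zeros(shape)
    else:
        du = rng.normal(0.0, sigma, shape)
        dv = rng.normal(0.0, sigma, shape)
    times = np.arange(n_frames) / frame_rate
    return VectorFieldSeries(x=x, y=y, times=times,
                             u=mean_speed + du, v=dv)


def synth_tunnel_track(profile: GustProfile, duration: float,
                       noise_px: float = 1.0, seed: int = 0,
                       frame_rate: float = tracking.FRAME_RATE_DEFAULT,
                       resolution: float = tracking.MM_PER_PX_DEFAULT
                       ) -> TrackSeries:
    """Pixel track of a marker riding on the translating tunnel.

    The profile is integrated to displacement, sampled at the frame rate,
    converted to pixels at ``resolution`` mm/px and corrupted with seeded
    Gaussian pixel noise on both coordinates.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_px < 0:
        raise ValueError("noise must be non-negative")
    n = int(np.floor(duration * frame_rate)) + 1
    frames = np.arange(n)
    t = frames / frame_rate
    disp = np.asarray(profile.displacement_at(t), float)   # m, along gust axis
    px = disp / (resolution * 1e-3)
    rng = np.random.default_rng(seed)
    x_px = np.full(n, 500.0)
    y_px = 3000.0 + px
    if noise_px > 0:
        x_px = x_px + rng.normal(0.0, noise_px, n)
        y_px = y_px + rng.normal(0.0, noise_px, n)
    return TrackSeries(frames=frames, x_px=x_px, y_px=y_px,
                       resolution=resolution, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# virtual diaspore and the demonstration scenario

@dataclass(frozen=True)
class VirtualDiaspore:
    """Bottom-heavy quadratic-drag body hovering in a vertical airstream."""

    body: BodySpec
    closure: AeroClosure
    inflow: np.ndarray
    medium: FluidMedium
    metadata: dict = field(default_factory=dict)


def virtual_diaspore(medium: FluidMedium = AIR,
                     u_t: float = DIASPORE_TERMINAL_VELOCITY) -> VirtualDiaspore:
    """Dandelion-like test body: seed below, pappus above.

    Centre of gravity near the seed, centre of buoyancy near the pappus
    centre (``r_hat = +x`` in the body frame, offset ``e > 0``), quadratic
    drag calibrated so the terminal velocity is exactly ``u_t``, and the
    tunnel inflow set to hover.  Mass, inertia, ``e`` and the drag area
    are plausible non-measured defaults.
    """
    body = BodySpec(
        mass=0.8e-6,                 # kg      (assumed, not measured)
        mean_density=400.0,          # kg/m^3  (assumed, not measured)
        length=14e-3,                # m, pappus diameter scale
        inertia=np.diag([2e-11, 2e-11, 2e-11]),  # kg m^2 (assumed, not measured)
        eccentricity=5e-3,           # m       (assumed, not measured)
        r_hat=X_UP,
    )
    closure = calibrate_closure_to_terminal_velocity(
        u_t, body, medium, family="quadratic", c_omega=1e-10)
    return VirtualDiaspore(
        body=body, closure=closure, inflow=u_t * X_UP, medium=medium,
        metadata={
            "terminal_velocity_m_s": u_t,
            "assumed_defaults": ["mass", "mean_density", "inertia",
                                  "eccentricity", "c_omega", "area"],
        })


def _sine_power_exponent(mean_over_peak: float) -> float:
    """Exponent p of a sin^p pulse whose mean/peak ratio is given.

    ``mean(sin^p(pi s), s in [0,1]) = Gamma((p+1)/2) / (sqrt(pi) Gamma(p/2+1))``.
    """

    def mean_fraction(p: float) -> float:
        return _gamma((p + 1) / 2) / (np.sqrt(np.pi) * _gamma(p / 2 + 1))

    return brentq(lambda p: mean_fraction(p) - mean_over_peak, 0.5, 20.0,
                  xtol=1e-12)


def demo_gust_profile(plateau: float = DEMO_PLATEAU_SPEED,
                      t_on: float = DEMO_GUST_ONSET,
                      t_stop: float = DEMO_GUST_STOP,
                      peak_decel: float = DEMO_PEAK_DECELERATION,
                      t_end: float = 0.6,
                      sample_rate: float = 3000.0) -> GustProfile:
    """The demonstration tunnel-motion profile as a tabulated gust.

    Constant translation at ``plateau`` until ``t_on``, then a smooth
    stopping pulse — acceleration ``a(t) = a_pk sin^p(pi (t-t_on)/dt)``
    with the exponent ``p`` chosen so the pulse both peaks at
    ``peak_decel`` and integrates to ``|plateau|`` over
    ``dt = t_stop - t_on`` — then at rest.  The acceleration is
    continuous (zero at both ends of the pulse), so the integrator sees
    no impulses.
    """
    dt = t_stop - t_on
    dv = -plateau
    mean_over_peak = dv / (peak_decel * dt)
    if not 0 < mean_over_peak < 1:
        raise ValueError("peak deceleration inconsistent with dv and duration")
    p = _sine_power_exponent(mean_over_peak)
    t = np.arange(0.0, t_end + 0.5 / sample_rate, 1.0 / sample_rate)
    s = np.clip((t - t_on) / dt, 0.0, 1.0)
    a = peak_decel * np.sin(np.pi * s) ** p
    # cumulative trapezoid of the pulse, rescaled so the stop is exact
    da = np.concatenate([[0.0], np.cumsum(0.5 * (a[1:] + a[:-1]) * np.diff(t))])
    da *= dv / da[-1]
    v = plateau + da
    v[t >= t_stop] = 0.0
    return GustProfile.tabulated(t, v)


@dataclass(frozen=True)
class DemoScenario:
    """Configured virtual-experiment: diaspore, hover inflow, stop gust."""

    diaspore: VirtualDiaspore
    gust: GustProfile
    frame: FrameSpec
    state0: BodyState
    gust_ratio: float

    def run(self, t_end: float = 4.0, n_out: int = 1200,
            rtol: float = 1e-8, atol: float = 1e-10,
            diagnostics: bool = False) -> "DemoResult":
        d = self.diaspore
        t_eval = np.linspace(0.0, t_end, n_out)
        traj = simulate(d.body, d.medium, d.closure, self.frame, self.state0,
                        (0.0, t_end), t_eval=t_eval, rtol=rtol, atol=atol,
                        diagnostics=diagnostics)
        theta = traj.tilt_angle()
        height = traj.position[:, 0]
        return DemoResult(trajectory=traj, theta=theta,
                          height_change=height - height[0],
                          gust_ratio=self.gust_ratio)


@dataclass(frozen=True)
class DemoResult:
    """Outputs of the demonstration run, tunnel frame."""

    trajectory: Trajectory
    theta: np.ndarray          #: rad, positive clockwise
    height_change: np.ndarray  #: m, relative to the initial hover height
    gust_ratio: float

    @property
    def max_theta(self) -> float:
        return float(np.max(self.theta))

    @property
    def final_theta(self) -> float:
        return float(self.theta[-1])

    @property
    def max_height_gain(self) -> float:
        return float(np.max(self.height_change))

    @property
    def final_height_gain(self) -> float:
        return float(self.height_change[-1])


def demo_scenario(medium: FluidMedium = AIR) -> DemoScenario:
    """Assemble the virtual gust-response experiment.

    The diaspore hovers upright; the tunnel translates at twice the
    terminal velocity and is smoothly brought to rest — a transverse gust
    of ratio 2 in the frame of the flyer.
    """
    d = virtual_diaspore(medium)
    gust = demo_gust_profile()
    frame = FrameSpec(tag="tunnel", gust=gust, inflow=d.inflow)
    g_r = gust_ratio(np.max(np.abs(gust.params["v"])),
                     DIASPORE_TERMINAL_VELOCITY)
    return DemoScenario(diaspore=d, gust=gust, frame=frame,
                        state0=BodyState.at_rest(), gust_ratio=g_r)
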