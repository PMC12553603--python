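"""Facility-characterisation statistics and pressure reconstruction.

Operates on gridded 2-D velocity-field time series (planar PIV style):
flow uniformity maps, turbulence-intensity maps, the Galilean shift of
measured fields into the tunnel frame, and reconstruction of the physical
pressure from the solver pressure (which is net of the hydrostatic
contributions of gravity and, during a gust, of the uniform horizontal
pressure gradient that accompanies the fluid acceleration).

Axes: ``x`` streamwise (vertical up), ``y`` streamnormal (horizontal,
the tunnel translation direction); ``u``/``v`` are the corresponding
velocity components.  Fields are single-camera, single-window: readers
reject inconsistent grids rather than stitching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VectorFieldSeries",
    "UniformityReport",
    "TurbulenceMap",
    "Window",
    "uniformity",
    "turbulence_intensity",
    "shift_frame",
    "physical_pressure_static",
    "physical_pressure_gust",
    "read_field_series",
    "write_field_series",
]


@dataclass(frozen=True)
class Window:
    """Rectangular sub-region [x0, x1] x [y0, y1] in metres (inclusive)."""

    x0: float
    x1: float
    y0: float
    y1: float

    def mask(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mx = (x >= self.x0) & (x <= self.x1)
        my = (y >= self.y0) & (y <= self.y1)
        if not mx.any() or not my.any():
            raise ValueError("window contains no grid points")
        return mx, my


@dataclass
class VectorFieldSeries:
    """Per-frame (u, v) snapshots on a fixed rectangular grid.

    ``u`` and ``v`` have shape ``(n_frames, nx, ny)`` indexed
    ``[frame, i_x, i_y]``.
    """

    x: np.ndarray        #: (nx,) strictly increasing, m
    y: np.ndarray        #: (ny,) strictly increasing, m
    times: np.ndarray    #: (n_frames,) s
    u: np.ndarray        #: streamwise component, m/s
    v: np.ndarray        #: streamnormal component, m/s

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.times = np.asarray(self.times, float)
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        for name, c in (("x", self.x), ("y", self.y), ("times", self.times)):
            if c.ndim != 1 or (c.size > 1 and np.any(np.diff(c) <= 0)):
                raise ValueError(f"{name} must be 1-d strictly increasing")
        shape = (self.times.size, self.x.size, self.y.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(
                f"u/v must have shape (n_frames, nx, ny) = {shape}")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class UniformityReport:
    """Time-averaged speed map normalised by its window mean."""

    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray            #: |u_bar|(x, y), m/s
    mean_speed: float            #: <|u_bar|> over the window
    normalised: np.ndarray       #: |u_bar| / <|u_bar|> over the window grid
    max_fractional_deviation: float


@dataclass(frozen=True)
class TurbulenceMap:
    """Pointwise turbulence intensity over a window.

    ``intensity`` is a masked array: points whose local time-mean speed is
    zero have undefined intensity and are masked rather than reported.
    """

    x: np.ndarray
    y: np.ndarray
    intensity: np.ma.MaskedArray
    window: Window

    @property
    def mean(self) -> float:
        return float(self.intensity.mean())


def uniformity(fields: VectorFieldSeries, window: Window) -> UniformityReport:
    """Flow-uniformity report: time-averaged speed over its window mean.

    Each velocity component is time-averaged pointwise; the magnitude of
    the averaged vector is normalised by its spatial mean over ``window``.
    The maximum of ``|normalised - 1|`` summarises the non-uniformity.
    """
    if fields.n_frames < 2:
        raise ValueError("uniformity needs at least 2 frames")
    mx, my = window.mask(fields.x, fields.y)
    u_bar = fields.u.mean(axis=0)
    v_bar = fields.v.mean(axis=0)
    speed = np.hypot(u_bar, v_bar)
    sub = speed[np.ix_(mx, my)]
    mean_speed = float(sub.mean())
    if mean_speed == 0:
        raise ValueError("window mean speed is zero; cannot normalise")
    normalised = sub / mean_speed
    return UniformityReport(
        x=fields.x[mx], y=fields.y[my], speed=sub, mean_speed=mean_speed,
        normalised=normalised,
        max_fractional_deviation=float(np.max(np.abs(normalised - 1.0))),
    )


def turbulence_intensity(fields: VectorFieldSeries,
                         window: Window) -> TurbulenceMap:
    """RMS velocity fluctuation normalised by the local time-mean speed.

    .. math::

        T_{u,v}(x,y) = \\frac{1}{|\\bar{\\boldsymbol u}(x,y)|}
        \\sqrt{\\tfrac12\\left(\\overline{(u-\\bar u)^2}
        + \\overline{(v-\\bar v)^2}\\right)}

    The divisor is the *local* time-averaged speed, not a window mean.
    Points with zero local mean speed are masked.
    """
    if fields.n_frames < 2:
        raise ValueError("turbulence intensity needs at least 2 frames")
    mx, my = window.mask(fields.x, fields.y)
    u = fields.u[:, mx][:, :, my]
    v = fields.v[:, mx][:, :, my]
    u_bar = u.mean(axis=0)
    v_bar = v.mean(axis=0)
    # variance is translation invariant; removing the first frame before
    # averaging keeps a strictly constant field at exactly zero intensity
    du = u - u[0]
    dv = v - v[0]
    var = (((du - du.mean(axis=0)) ** 2).mean(axis=0)
           + ((dv - dv.mean(axis=0)) ** 2).mean(axis=0))
    rms = np.sqrt(var / 2.0)
    speed = np.hypot(u_bar, v_bar)
    mask = speed == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(mask, 0.0, rms / np.where(mask, 1.0, speed))
    return TurbulenceMap(x=fields.x[mx], y=fields.y[my],
                         intensity=np.ma.MaskedArray(t, mask=mask),
                         window=window)


def shift_frame(fields: VectorFieldSeries, gust) -> VectorFieldSeries:
    """Galilean shift of measured fields into the tunnel frame.

    Subtracts the (spatially uniform) instantaneous tunnel velocity from
    the streamnormal component frame by frame: ``u' = u - u_G``.  Spatial
    gradients are untouched; a uniform translating flow in the Earth
    frame becomes quiescent in the tunnel frame.

    ``gust`` is a :class:`~gustfall.gusts.GustProfile` or any callable
    mapping time to the scalar tunnel speed.
    """
    speed = gust.speed_at if hasattr(gust, "speed_at") else gust
    u_G = np.asarray([speed(t) for t in fields.times], dtype=float)
    if not np.all(np.isfinite(u_G)):
        raise ValueError("tunnel speed undefined at some frame times")
    return VectorFieldSeries(
        x=fields.x, y=fields.y, times=fields.times,
        u=fields.u.copy(), v=fields.v - u_G[:, None, None],
    )


def physical_pressure_static(p, x, x_out: float, g: float):
    """Physical pressure from solver pressure: ``p_ph = p - g (x - x_out)``.

    ``p`` is the pressure net of the hydrostatic contribution (per unit
    density scaling), ``x`` the streamwise vertical-up coordinate and
    ``x_out`` the outlet reference where both agree.
    """
    return np.asarray(p, float) - g * (np.asarray(x, float) - x_out)


def physical_pressure_gust(p_prime, x_prime, y_prime, x_out_prime: float,
                           g: float, a_G: float):
    """Physical pressure in the gust frame.

    Adds, on top of the vertical hydrostatic term, the *horizontal*
    hydrostatic pressure of the uniform gust acceleration:
    ``p_ph = p' - g (x' - x'_out) - a_G y'``, with ``y'`` centred in the
    tunnel section along the gust direction.  Its horizontal gradient is
    the uniform ``-a_G``; both added terms are linear in the coordinates
    and contribute nothing to the pressure Laplacian.
    """
    return (np.asarray(p_prime, float)
            - g * (np.asarray(x_prime, float) - x_out_prime)
            - a_G * np.asarray(y_prime, float))


# ---------------------------------------------------------------------------
# delimited-text IO (long format: frame, t, x, y, u, v)

def write_field_series(fields: VectorFieldSeries, path) -> None:
    nf, nx, ny = fields.u.shape
    frame_idx = np.repeat(np.arange(nf), nx * ny)
    t = np.repeat(fields.times, nx * ny)
    xx, yy = np.meshgrid(fields.x, fields.y, indexing="ij")
    pd.DataFrame({
        "frame": frame_idx,
        "t": t,
        "x": np.tile(xx.ravel(), nf),
        "y": np.tile(yy.ravel(), nf),
        "u": fields.u.reshape(nf, -1).ravel(),
        "v": fields.v.reshape(nf, -1).ravel(),
    }).to_csv(path, index=False)


def read_field_series(path) -> VectorFieldSeries:
    """Read a long-format field series; rejects ragged/inconsistent grids."""
    df = pd.read_csv(path)
    required = {"frame", "t", "x", "y", "u", "v"}
    if not required.issubset(df.columns):
        missing = sorted(required - set(df.columns))
        raise ValueError(f"field file missing columns: {missing}")
    x = np.unique(df["x"].to_numpy())
    y = np.unique(df["y"].to_numpy())
    frames = np.unique(df["frame"].to_numpy())
    nf, nx, ny = frames.size, x.size, y.size
    if len(df) != nf * nx * ny:
        raise ValueError("field file is not a complete rectangular grid")
    df = df.sort_values(["frame", "x", "y"], kind="stable")
    times = df.groupby("frame")["t"].first().to_numpy()
    u = df["u"].to_numpy().reshape(nf, nx, ny)
    v = df["v"].to_numpy().reshape(nf, nx, ny)
    return VectorFieldSeries(x=x, y=y, times=times, u=u, v=v)
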