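"""Kinematics extraction from high-speed marker tracks.

Pixel tracks (marker on the tunnel, tip and centroid of a flyer) are
converted to metres, de-noised with a centred ten-point moving average,
and differentiated with second-order finite differences to velocity and
acceleration.  The tunnel's own track yields the realised gust profile;
tip + centroid tracks yield the stem angle, positive clockwise.

Track coordinates follow the package convention: ``x_px`` along the
vertical-up axis, ``y_px`` horizontal along the tunnel translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gusts import GustProfile, Y_GUST

__all__ = [
    "TrackSeries",
    "KinematicsSeries",
    "pixels_to_metres",
    "moving_average",
    "differentiate",
    "tunnel_gust_profile_from_track",
    "stem_angle",
    "track_kinematics",
    "read_track",
    "write_track",
]

MM_PER_PX_DEFAULT = 0.0805
FRAME_RATE_DEFAULT = 750.0
MOVING_AVERAGE_WINDOW = 10


@dataclass(frozen=True)
class TrackSeries:
    """Marker pixel track with imaging metadata.

    ``resolution`` is in mm per pixel, ``frame_rate`` in frames/s; frame
    times are ``frame / frame_rate``.
    """

    frames: np.ndarray        #: (n,) integer frame indices, consecutive
    x_px: np.ndarray          #: (n,) vertical pixel coordinate
    y_px: np.ndarray          #: (n,) horizontal pixel coordinate
    resolution: float = MM_PER_PX_DEFAULT
    frame_rate: float = FRAME_RATE_DEFAULT

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=int)
        x = np.asarray(self.x_px, dtype=float)
        y = np.asarray(self.y_px, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("track must contain at least one frame")
        if x.shape != f.shape or y.shape != f.shape:
            raise ValueError("frame/x/y arrays must have matching length")
        if f.size > 1 and not np.all(np.diff(f) == 1):
            raise ValueError("frame indices must be consecutive (constant rate)")
        if not self.resolution or self.resolution <= 0:
            raise ValueError("resolution (mm/px) must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "x_px", x)
        object.__setattr__(self, "y_px", y)

    def __len__(self) -> int:
        return self.frames.size

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.frame_rate


@dataclass(frozen=True)
class KinematicsSeries:
    """Position/velocity/acceleration time series in SI units."""

    t: np.ndarray             #: s
    position: np.ndarray      #: (n, 2) m, columns (x, y)
    velocity: np.ndarray      #: (n, 2) m/s
    acceleration: np.ndarray  #: (n, 2) m/s^2
    theta: np.ndarray | None = None  #: rad, positive clockwise

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t": self.t,
            "x": self.position[:, 0], "y": self.position[:, 1],
            "vx": self.velocity[:, 0], "vy": self.velocity[:, 1],
            "ax": self.acceleration[:, 0], "ay": self.acceleration[:, 1],
        })
        if self.theta is not None:
            df["theta"] = self.theta
        return df


def pixels_to_metres(track: TrackSeries) -> np.ndarray:
    """Convert the pixel track to metres; shape (n, 2), columns (x, y)."""
    scale = track.resolution * 1e-3
    return np.column_stack([track.x_px, track.y_px]) * scale


def moving_average(series: np.ndarray, window: int = MOVING_AVERAGE_WINDOW) -> np.ndarray:
    """Centred moving average preserving series length.

    For an even ``window`` the two extreme samples get half weight
    (trapezoidal weights over a symmetric span), which keeps straight
    lines invariant at interior points.  Near the edges the window
    shrinks symmetrically instead of trimming the series, so event
    timestamps stay aligned.  Works along the first axis.
    """
    y = np.asarray(series, dtype=float)
    n = y.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    h, odd = divmod(window, 2)
    if odd:
        weights = np.ones(window)
    else:
        weights = np.ones(window + 1)
        weights[0] = weights[-1] = 0.5
    out = np.empty_like(y)
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        if hi == 0:
            out[i] = y[i]
            continue
        if odd or hi < h:
            w = np.ones(2 * hi + 1)
        else:
            w = weights
        seg = y[i - hi:i + hi + 1]
        out[i] = (w.reshape(-1, *([1] * (y.ndim - 1))) * seg).sum(axis=0) / w.sum()
    return out


def differentiate(series: np.ndarray, rate: float) -> np.ndarray:
    """Second-order finite-difference time derivative at sampling ``rate``.

    Central differences at interior points, second-order one-sided at the
    ends; exact for quadratics everywhere.
    """
    y = np.asarray(series, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return np.gradient(y, 1.0 / rate, axis=0, edge_order=2)


def track_kinematics(track: TrackSeries,
                     window: int = MOVING_AVERAGE_WINDOW) -> KinematicsSeries:
    """Pixel track -> de-noised SI position, velocity and acceleration."""
    pos = moving_average(pixels_to_metres(track), window)
    vel = differentiate(pos, track.frame_rate)
    acc = differentiate(vel, track.frame_rate)
    return KinematicsSeries(t=track.times, position=pos, velocity=vel,
                            acceleration=acc)


def tunnel_gust_profile_from_track(track: TrackSeries,
                                   window: int = MOVING_AVERAGE_WINDOW,
                                   direction: np.ndarray = Y_GUST) -> GustProfile:
    """Recover the realised gust (tunnel) velocity profile from its marker.

    Pipeline: pixels to metres, centred moving average, second-order
    differentiation of the horizontal displacement; the sampled velocity
    becomes a tabulated profile (whose acceleration is its own centred
    finite difference).
    """
    if len(track) < max(3, window):
        raise ValueError("track too short to extract a gust profile")
    kin = track_kinematics(track, window)
    return GustProfile.tabulated(kin.t, kin.velocity[:, 1], direction=direction)


def stem_angle(tip_track: TrackSeries, centroid_track: TrackSeries) -> np.ndarray:
    """Stem angle from vertical, rad, positive clockwise (top towards +y).

    The body axis is taken from the tracked tip (achene/seed end, at the
    bottom when upright) to the centroid (pappus region): upright gives 0;
    mirroring the ``y`` axis negates the angle.
    """
    if len(tip_track) != len(centroid_track) or not np.array_equal(
            tip_track.frames, centroid_track.frames):
        raise ValueError("tip and centroid tracks must be synchronised")
    tip = pixels_to_metres(tip_track)
    cen = pixels_to_metres(centroid_track)
    axis = cen - tip
    norms = np.linalg.norm(axis, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("coincident tip/centroid points: angle undefined")
    return np.arctan2(axis[:, 1], axis[:, 0])


# ---------------------------------------------------------------------------
# delimited-text IO (header: frame, x_px, y_px; metadata as '#' comments)

def write_track(track: TrackSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# resolution_mm_per_px = {track.resolution!r}\n")
        fh.write(f"# frame_rate_per_s = {track.frame_rate!r}\n")
        pd.DataFrame({"frame": track.frames, "x_px": track.x_px,
                      "y_px": track.y_px}).to_csv(fh, index=False)


def read_track(path, resolution: float | None = None,
               frame_rate: float | None = None) -> TrackSeries:
    """Read a track file; metadata comments supply resolution/frame rate
    unless overridden by the keyword arguments."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = 0
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh)
    required = {"frame", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"track file missing columns: {sorted(required - set(df.columns))}")
    res = resolution if resolution is not None else meta.get("resolution_mm_per_px")
    rate = frame_rate if frame_rate is not None else meta.get("frame_rate_per_s")
    if res is None:
        raise ValueError("resolution not given and not found in track metadata")
    if rate is None:
        raise ValueError("frame rate not given and not found in track metadata")
    return TrackSeries(frames=df["frame"].to_numpy(),
                       x_px=df["x_px"].to_numpy(),
                       y_px=df["y_px"].to_numpy(),
                       resolution=res, frame_rate=rate)
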