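"""Population observables from tracked colony trajectories.

Implements the boundary-corrected kernel density estimate across the
chamber, running ensemble velocity statistics, and pooled heading /
turn-angle samples used to discriminate navigation strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._util import angular_distance_from_up, moving_average, wrap_angle

logger = logging.getLogger(__name__)


@dataclass
class TrackSet:
    """Frame-indexed 2D trajectories in micrometers.

    ``data`` columns: track_id, frame, x_um, y_um.  ``gradient_sign`` maps a
    time in seconds to +1 (gradient up), -1 (down) or 0 (none); by default
    there is no gradient tag.
    """

    data: pd.DataFrame
    frame_interval: float = 0.1
    y_extent: tuple = (0.0, 1000.0)
    gradient_sign: object = None
    _groups: dict = field(default=None, repr=False, compare=False)

    REQUIRED = ("track_id", "frame", "x_um", "y_um")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing track columns: {missing}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.data = self.data.sort_values(["track_id", "frame"]).reset_index(
            drop=True)
        frames = self.data.groupby("track_id")["frame"]
        if (frames.apply(lambda f: np.any(np.diff(f) <= 0))).any():
            raise ValueError("frames must be strictly increasing per track")

    def filtered(self, min_length: int = 3) -> "TrackSet":
        """Drop spurious tracks shorter than ``min_length`` frames."""
        counts = self.data.groupby("track_id")["frame"].size()
        keep = counts.index[counts >= min_length]
        return TrackSet(self.data[self.data["track_id"].isin(keep)].copy(),
                        self.frame_interval, self.y_extent,
                        self.gradient_sign)

    def sign_at(self, t):
        """Gradient-direction flag at time(s) t; accepts scalars or arrays."""
        t = np.asarray(t, dtype=float)
        if self.gradient_sign is None:
            return np.zeros_like(t)
        if callable(self.gradient_sign):
            out = self.gradient_sign(t)
            out = np.asarray(out, dtype=float)
            if out.shape != t.shape:  # non-vectorized callable
                out = np.array([float(self.gradient_sign(tt))
                                for tt in np.atleast_1d(t)]).reshape(t.shape)
            return out
        return np.full_like(t, float(self.gradient_sign))

    def groups(self):
        if self._groups is None:
            self._groups = {
                tid: g[["frame", "x_um", "y_um"]].to_numpy()
                for tid, g in self.data.groupby("track_id")
            }
        return self._groups

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval: float = 0.1,
                 y_extent: tuple = (0.0, 1000.0)) -> "TrackSet":
        return cls(pd.read_csv(path), frame_interval=frame_interval,
                   y_extent=y_extent)


# ---------------------------------------------------------------------------
# Density estimation

def density_profile(positions, sigma: float, bounds: tuple,
                    grid: np.ndarray | int = 200):
    """Boundary-corrected Gaussian KDE of positions on [y0, y1].

    Each kernel is divided by its own mass inside the domain (truncated
    Gaussian normalizer), which removes the density depression at the walls;
    the sum is then normalized to integrate to 1.

    Returns ``(y_grid, rho)`` with rho in 1/um.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1)
    if pos.size == 0:
        raise ValueError("no positions supplied")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y0, y1 = map(float, bounds)
    if y1 <= y0:
        raise ValueError("invalid domain bounds")
    if np.isscalar(grid):
        y = np.linspace(y0, y1, int(grid))
    else:
        y = np.asarray(grid, dtype=float)

    # eta(y) = sum_i K(y_i - y) / integral_domain K(y' - y) dy'
    kernels = np.exp(-((pos[None, :] - y[:, None]) ** 2) / (2 * sigma**2))
    denom = sigma * np.sqrt(2 * np.pi) * (
        ndtr((y1 - y) / sigma) - ndtr((y0 - y) / sigma)
    )
    eta = kernels.sum(axis=1) / denom
    rho = eta / np.trapezoid(eta, y)
    return y, rho


# ---------------------------------------------------------------------------
# Velocity statistics

def _track_velocities(arr: np.ndarray, frame_interval: float):
    """Central-difference velocities for one track array (frame, x, y).

    Only rows whose neighbours are consecutive frames contribute.
    Returns (frames, vx, vy) at the interior usable frames.
    """
    frames = arr[:, 0].astype(int)
    if len(frames) < 3:
        return None
    ok = (frames[2:] - frames[:-2]) == 2  # both neighbours present
    if not ok.any():
        return None
    vx = (arr[2:, 1] - arr[:-2, 1]) / (2 * frame_interval)
    vy = (arr[2:, 2] - arr[:-2, 2]) / (2 * frame_interval)
    return frames[1:-1][ok], vx[ok], vy[ok]


def velocity_series(tracks: TrackSet, smooth_window: float = 0.0
                    ) -> pd.DataFrame:
    """Per-frame ensemble means of speed and component velocities.

    Velocities are central differences over one frame per track; tracks too
    short for the stencil are skipped (logged).  ``smooth_window`` (s)
    applies a centered moving average to the output series.

    Returns a DataFrame with columns t, v, vx, vy, n.
    """
    if smooth_window and smooth_window < tracks.frame_interval:
        raise ValueError("smoothing window shorter than the frame interval")
    per_frame: dict[int, list] = {}
    n_skipped = 0
    for tid, arr in tracks.groups().items():
        res = _track_velocities(arr, tracks.frame_interval)
        if res is None:
            n_skipped += 1
            continue
        frames, vx, vy = res
        speed = np.hypot(vx, vy)
        for f, a, b, s in zip(frames, vx, vy, speed):
            per_frame.setdefault(int(f), []).append((a, b, s))
    if n_skipped:
        logger.info("velocity_series: skipped %d short tracks", n_skipped)
    if not per_frame:
        raise ValueError("no track long enough for the velocity stencil")
    frames = np.array(sorted(per_frame))
    stats = np.array([np.mean(per_frame[f], axis=0) for f in frames])
    counts = np.array([len(per_frame[f]) for f in frames])
    vx, vy, v = stats[:, 0], stats[:, 1], stats[:, 2]
    if smooth_window:
        w = max(1, int(round(smooth_window / tracks.frame_interval)))
        v, vx, vy = (moving_average(a, w) for a in (v, vx, vy))
    return pd.DataFrame({
        "t": frames * tracks.frame_interval,
        "v": v, "vx": vx, "vy": vy, "n": counts,
    })


def alignment_samples(tracks: TrackSet, windows) -> pd.DataFrame:
    """Per-colony (alignment, speed) samples inside post-swap windows.

    ``windows`` is an iterable of (t_start, t_end) during which the gradient
    direction flag of the TrackSet is valid.  Alignment is c_hat * vy / v.
    """
    rows = []
    for tid, arr in tracks.groups().items():
        res = _track_velocities(arr, tracks.frame_interval)
        if res is None:
            continue
        frames, vx, vy = res
        t = frames * tracks.frame_interval
        speed = np.hypot(vx, vy)
        for (t0, t1) in windows:
            sel = (t >= t0) & (t <= t1) & (speed > 0)
            if not sel.any():
                continue
            signs = tracks.sign_at(t[sel])
            rows.append(pd.DataFrame({
                "alignment": signs * vy[sel] / speed[sel],
                "speed": speed[sel],
            }))
    if not rows:
        raise ValueError("no samples inside the supplied windows")
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Angle statistics

def angle_samples(tracks: TrackSet, delta_t: float = 0.65,
                  windows=None) -> tuple[np.ndarray, np.ndarray]:
    """Pooled heading samples theta and turn-angle samples dphi.

    Headings come from single-frame displacements; when the gradient points
    down (flag -1) headings are folded theta -> -theta so pi/2 always points
    up the gradient.  The turn angle over the lag ``delta_t`` is positive
    for turns toward the gradient:

        dphi = |theta(t) - pi/2| - |theta(t + delta_t) - pi/2|

    with angular distances measured on the circle.
    """
    steps = delta_t / tracks.frame_interval
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError("delta_t must be a multiple of the frame interval")
    steps = int(round(steps))
    thetas, dphis = [], []
    for tid, arr in tracks.groups().items():
        frames = arr[:, 0].astype(int)
        consecutive = np.diff(frames) == 1
        if not consecutive.any():
            continue
        dx = np.diff(arr[:, 1])
        dy = np.diff(arr[:, 2])
        theta = np.arctan2(dy, dx)[consecutive]
        tf = frames[:-1][consecutive]
        t = tf * tracks.frame_interval
        if windows is not None:
            sel = np.zeros(len(t), dtype=bool)
            for (t0, t1) in windows:
                sel |= (t >= t0) & (t <= t1)
            theta, tf, t = theta[sel], tf[sel], t[sel]
        if len(theta) == 0:
            continue
        signs = tracks.sign_at(t)
        theta = wrap_angle(np.where(signs < 0, -theta, theta))
        thetas.append(theta)
        # pair samples separated by exactly `steps` frames
        idx = np.searchsorted(tf, tf + steps)
        valid = (idx < len(tf)) & (tf[np.minimum(idx, len(tf) - 1)] == tf + steps)
        if valid.any():
            d = angular_distance_from_up(theta)
            dphis.append(d[valid] - d[idx[valid]])
    if not thetas:
        raise ValueError("no usable displacement pairs in the track set")
    dphi = (np.concatenate(dphis) if dphis
            else np.empty(0, dtype=float))
    return np.concatenate(thetas), dphi
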