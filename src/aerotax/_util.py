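"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np


def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -((-theta + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


def angular_distance_from_up(theta):
    """Angular distance of heading(s) from the up direction (pi/2), in [0, pi]."""
    return np.abs(wrap_angle(np.asarray(theta, dtype=float) - np.pi / 2.0))


def delta_phi_from_theta(theta_t, theta_t_dt):
    """Angle turned toward the up direction between two headings.

    Positive when the second heading is closer to pi/2 than the first.
    """
    return angular_distance_from_up(theta_t) - angular_distance_from_up(theta_t_dt)


def moving_average(x, window: int):
    """Centered moving average with truncated windows at the edges."""
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    n = x.size
    csum = np.cumsum(np.insert(x, 0, 0.0))
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + window - half, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
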