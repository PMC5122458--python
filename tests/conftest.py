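import numpy as np
import pytest

from aerotax.oxygen_sim import ChamberProfile, DeviceGeometry


@pytest.fixture(scope="session")
def coarse_geometry():
    """Default device at the coarsest resolution that resolves all features."""
    return DeviceGeometry(dy=50.0, dz=25.0)


def make_constant_profile(y, c_value, dc_value, t_end=1e6):
    """Time-constant chamber profile with uniform c and gradient."""
    y = np.asarray(y, dtype=float)
    t = np.array([0.0, t_end])
    c = np.full((2, y.size), float(c_value))
    dc = np.full((2, y.size), float(dc_value))
    return ChamberProfile(y=y, t=t, c=c, dc_dy=dc)


def make_exponential_profile(y, c0, k, t_end=1e6):
    """Profile with c = c0 * exp(k y): constant relative gradient k."""
    y = np.asarray(y, dtype=float)
    t = np.array([0.0, t_end])
    c = np.tile(c0 * np.exp(k * y), (2, 1))
    dc = k * c
    return ChamberProfile(y=y, t=t, c=c, dc_dy=dc)


@pytest.fixture
def straight_up_tracks():
    """Five colonies moving straight +y at 10 um/s, 10 fps, 50 frames."""
    import pandas as pd

    from aerotax.trajectory_stats import TrackSet

    frames = np.arange(50)
    rows = []
    for tid in range(5):
        x = np.full(50, 100.0 + 30 * tid)
        y = 100.0 + 1.0 * frames  # 1 um per frame = 10 um/s
        rows.append(pd.DataFrame({
            "track_id": tid, "frame": frames, "x_um": x, "y_um": y,
        }))
    df = pd.concat(rows, ignore_index=True)
    return TrackSet(df, frame_interval=0.1, y_extent=(0.0, 400.0),
                    gradient_sign=lambda t: np.ones_like(np.asarray(t)))
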