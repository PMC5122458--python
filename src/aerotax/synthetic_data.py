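"""Synthetic inputs with known ground truth for every pipeline stage.

Canned gas protocols solved into oxygen fields, biased-swimmer trajectory
ensembles coupled to those fields through the gradient-response functional,
and toy bright-field videos for the tracking stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import oxygen_sim
from ._util import wrap_angle
from .keller_segel import ResponseModel, response_velocity
from .navigation import StrategyParams
from .oxygen_sim import ChamberProfile, DeviceGeometry, GasProtocol
from .tracking import ImageStack
from .trajectory_stats import TrackSet

SCENARIOS = ("flip", "air_air", "n2_n2", "fig_protocol")


def make_protocol(name: str, t_end: float) -> GasProtocol:
    """Canned gas schedules mirroring the experimental sections."""
    if name == "flip":
        return GasProtocol(((0.0, "air", "nitrogen"),
                            (t_end / 2, "nitrogen", "air")))
    if name == "air_air":
        return GasProtocol(((0.0, "air", "air"),))
    if name == "n2_n2":
        return GasProtocol(((0.0, "nitrogen", "nitrogen"),))
    if name == "fig_protocol":
        # gradient -> flipped gradient -> uniform air -> nitrogen only -> gradient
        seg = t_end / 5
        return GasProtocol((
            (0.0, "air", "nitrogen"),
            (seg, "nitrogen", "air"),
            (2 * seg, "air", "air"),
            (3 * seg, "nitrogen", "nitrogen"),
            (4 * seg, "air", "nitrogen"),
        ))
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def make_field_scenario(
    name: str,
    *,
    t_end: float = 3600.0,
    geometry: DeviceGeometry | None = None,
    dt: float = 5.0,
    output_every: float = 30.0,
    c0: float | None = None,
    z_eval: float = 100.0,
):
    """Solve a canned protocol into an oxygen field and chamber profile.

    Returns ``(protocol, field, profile)``.  The initial condition defaults
    to 20% O2 except for the pure-gradient 'flip' scenario, which starts
    from its left-high steady state approximation (uniform 10%).
    """
    geometry = geometry or DeviceGeometry()
    protocol = make_protocol(name, t_end)
    if c0 is None:
        c0 = 10.0 if name == "flip" else 20.0
    fld = oxygen_sim.solve_diffusion(
        geometry, None, protocol, dt=dt, t_end=t_end, c0=c0,
        output_every=output_every,
    )
    profile = oxygen_sim.chamber_profile(fld, z_eval)
    return protocol, fld, profile


@dataclass
class ScenarioConfig:
    """Configuration for a synthetic trajectory ensemble."""

    profile: ChamberProfile
    strategy: StrategyParams
    response: ResponseModel
    n_colonies: int = 150
    duration: float = 600.0
    frame_interval: float = 0.1
    substeps: int = 10          # SDE substeps per frame
    jitter: float = 0.0         # um, detection position noise
    dropout: float = 0.0        # per-frame detection dropout probability
    seed: int = 0
    x_extent: tuple = (0.0, 1000.0)

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def local_bias(response: ResponseModel, strategy: StrategyParams,
               c: np.ndarray, dc_dy: np.ndarray) -> np.ndarray:
    """Signed stochastic bias eps(y, t) implied by the response functional.

    The response magnitude vt = |V[c]| is converted to a bias through the
    inversion eps = 2 v vt / (v^2 + vt^2) of the stationary drift relation,
    signed by the gradient direction, and clipped to |eps| <= 0.999.
    """
    v_resp = response_velocity(response, c, dc_dy)
    vt = np.abs(v_resp)
    eps = 2.0 * strategy.v * vt / (strategy.v**2 + vt**2)
    return np.clip(np.sign(v_resp) * eps, -0.999, 0.999)


def generate_tracks(config: ScenarioConfig):
    """Simulate a biased swimmer ensemble coupled to the oxygen profile.

    Headings follow the modulated-rotational-diffusion dynamics with the
    local bias from :func:`local_bias`; positions integrate the heading at
    the swimming speed, with specular reflection at the chamber walls in y.
    Detection noise (jitter) and dropout produce the observed TrackSet;
    the noiseless ground truth is returned alongside.

    Returns ``(observed: TrackSet, truth: dict)``.
    """
    prof = config.profile
    if prof.t[-1] < config.duration - 1e-9:
        raise ValueError("oxygen profile does not cover the scenario duration")
    rng = np.random.default_rng(config.seed)
    n = config.n_colonies
    y0, y1 = float(prof.y[0]), float(prof.y[-1])
    x0, x1 = config.x_extent
    sp = config.strategy

    n_frames = int(round(config.duration / config.frame_interval)) + 1
    dt = config.frame_interval / config.substeps

    x = rng.uniform(x0, x1, size=n)
    y = rng.uniform(y0, y1, size=n)
    theta = rng.uniform(-np.pi, np.pi, size=n)

    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    ths = np.empty((n_frames, n))
    xs[0], ys[0], ths[0] = x, y, theta

    sqdt = np.sqrt(dt)
    for f in range(1, n_frames):
        t_frame = f * config.frame_interval
        c_row, dc_row = prof.at_time(t_frame)
        for _ in range(config.substeps):
            c_loc = np.interp(y, prof.y, c_row)
            dc_loc = np.interp(y, prof.y, dc_row)
            eps = local_bias(config.response, sp, c_loc, dc_loc)
            amp = 2.0 * sp.dr * (1.0 - eps * np.sin(theta))
            theta = theta + np.sqrt(np.maximum(amp, 0.0)) * \
                rng.standard_normal(n) * sqdt
            theta = wrap_angle(theta)
            x = x + sp.v * np.cos(theta) * dt
            y = y + sp.v * np.sin(theta) * dt
            # specular reflection at the chamber walls
            over = y > y1
            under = y < y0
            y = np.where(over, 2 * y1 - y, y)
            y = np.where(under, 2 * y0 - y, y)
            theta = wrap_angle(np.where(over | under, -theta, theta))
        xs[f], ys[f], ths[f] = x, y, theta

    frames = np.arange(n_frames)
    truth_df = pd.DataFrame({
        "track_id": np.repeat(np.arange(n), n_frames),
        "frame": np.tile(frames, n),
        "x_um": xs.T.reshape(-1),
        "y_um": ys.T.reshape(-1),
        "theta": ths.T.reshape(-1),
    })

    obs = truth_df[["track_id", "frame", "x_um", "y_um"]].copy()
    if config.jitter > 0:
        obs["x_um"] += rng.normal(0.0, config.jitter, size=len(obs))
        obs["y_um"] += rng.normal(0.0, config.jitter, size=len(obs))
    if config.dropout > 0:
        keep = rng.random(len(obs)) >= config.dropout
        obs = obs[keep]

    def gradient_sign(t):
        _, dc = prof.at_time(float(np.mean(np.atleast_1d(t))))
        mid = dc[len(dc) // 2]
        s = np.sign(mid) if abs(mid) > 1e-6 else 0.0
        return np.full(np.shape(t), s) if np.ndim(t) else s

    observed = TrackSet(obs.reset_index(drop=True),
                        frame_interval=config.frame_interval,
                        y_extent=(y0, y1), gradient_sign=gradient_sign)
    truth = {
        "positions": truth_df,
        "params": sp,
        "response": config.response,
        "seed": config.seed,
    }
    return observed, truth


def render_video(
    tracks: TrackSet,
    *,
    pixel_size: float = 2.0,
    blob_sigma_px: float = 2.5,
    snr: float = 10.0,
    noise_sd: float = 10.0,
    background_level: float = 100.0,
    margin_px: int = 10,
    shape: tuple | None = None,
    seed: int = 0,
):
    """Render Gaussian blobs along tracks onto a noisy background.

    Blob amplitude is ``snr * noise_sd``.  Returns ``(stack, truth)`` where
    truth is a DataFrame of planted pixel positions per frame.
    """
    rng = np.random.default_rng(seed)
    df = tracks.data
    n_frames = int(df["frame"].max()) + 1 if len(df) else 1
    if shape is None:
        if len(df):
            w = int(np.ceil(df["x_um"].max() / pixel_size)) + 2 * margin_px
            h = int(np.ceil(df["y_um"].max() / pixel_size)) + 2 * margin_px
        else:
            w = h = 64
        shape = (h, w)
    h, w = shape
    frames = background_level + rng.normal(0.0, noise_sd,
                                           size=(n_frames, h, w))
    amp = snr * noise_sd
    half = int(np.ceil(4 * blob_sigma_px))
    truth_rows = []
    for _, row in df.iterrows():
        f = int(row["frame"])
        cx = row["x_um"] / pixel_size + margin_px
        cy = row["y_um"] / pixel_size + margin_px
        truth_rows.append((int(row["track_id"]), f, cx, cy))
        c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        c0, c1 = max(0, c0), min(w, c1)
        r0, r1 = max(0, r0), min(h, r1)
        if c0 >= c1 or r0 >= r1:
            continue
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        frames[f, r0:r1, c0:c1] += amp * np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2 * blob_sigma_px**2)
        )
    stack = ImageStack(frames, fps=1.0 / tracks.frame_interval,
                       pixel_size=pixel_size)
    truth = pd.DataFrame(truth_rows,
                         columns=["track_id", "frame", "x_px", "y_px"])
    return stack, truth
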