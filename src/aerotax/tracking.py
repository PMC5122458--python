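"""Colony detection and proximity linking in bright-field image stacks.

Pipeline: running-median background estimation, background subtraction,
difference-of-Gaussians band-pass, Gaussian smoothing, local-maxima
detection with sub-pixel centroid refinement, and greedy nearest-neighbor
linking with a short gap-bridging memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .trajectory_stats import TrackSet


@dataclass
class ImageStack:
    """Grayscale video: ``frames`` has shape (T, H, W)."""

    frames: np.ndarray
    fps: float = 10.0
    pixel_size: float = 1.0  # um per pixel

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("stack must be (T, H, W)")
        if self.fps <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.fps


def background_model(stack: ImageStack, window: float = 2.5) -> np.ndarray:
    """Per-pixel running temporal median over ``window`` seconds.

    Edge frames use truncated windows.  Returns an array shaped like
    ``stack.frames``.
    """
    n_frames = int(round(window * stack.fps))
    if n_frames < 3:
        raise ValueError("background window must span at least 3 frames")
    half = n_frames // 2
    t_total = stack.frames.shape[0]
    out = np.empty_like(stack.frames)
    for t in range(t_total):
        lo = max(0, t - half)
        hi = min(t_total, t + half + 1)
        out[t] = np.median(stack.frames[lo:hi], axis=0)
    return out


def detect(
    stack: ImageStack,
    background: np.ndarray | None = None,
    *,
    highpass_px: float = 20.0,
    lowpass_px: float = 2.0,
    gaussian_sigma: float = 2.0,
    threshold: float | None = None,
    threshold_nsigma: float = 3.0,
    min_separation_px: int = 3,
) -> list[pd.DataFrame]:
    """Per-frame detections as DataFrames (x_px, y_px, intensity).

    Frames are background subtracted, band-pass filtered (difference of
    Gaussians between ``lowpass_px`` and ``highpass_px``), Gaussian smoothed,
    and local maxima above threshold are refined to sub-pixel centroids.
    If ``threshold`` is None it is set per frame to ``threshold_nsigma``
    robust (MAD-based) noise standard deviations.  Blobs closer than the
    smoothing scale may merge into a single detection.
    """
    if highpass_px <= lowpass_px:
        raise ValueError("band-pass radii inverted: need highpass > lowpass")
    if background is None:
        background = background_model(stack)
    detections = []
    for t in range(stack.frames.shape[0]):
        img = stack.frames[t] - background[t]
        bp = gaussian_filter(img, lowpass_px) - gaussian_filter(img, highpass_px)
        sm = gaussian_filter(bp, gaussian_sigma)
        if threshold is None:
            mad = np.median(np.abs(sm - np.median(sm)))
            thr = threshold_nsigma * 1.4826 * mad
            if thr <= 0:
                thr = np.inf  # blank noise-free frame: nothing to detect
        else:
            thr = threshold
        # exclude a small border margin where the band-pass filter rings
        peaks = peak_local_max(sm, min_distance=min_separation_px,
                               threshold_abs=thr,
                               exclude_border=min_separation_px)
        rows = []
        for (r, c) in peaks:
            rr, cc = _subpixel_centroid(sm, r, c)
            rows.append((cc, rr, sm[r, c]))
        detections.append(pd.DataFrame(rows, columns=["x_px", "y_px",
                                                      "intensity"]))
    return detections


def _subpixel_centroid(img: np.ndarray, r: int, c: int,
                       half: int = 3) -> tuple[float, float]:
    """Intensity-weighted centroid in a (2*half+1)^2 window around a peak."""
    r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
    c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
    patch = img[r0:r1, c0:c1]
    w = np.clip(patch, 0.0, None)
    tot = w.sum()
    if tot <= 0:
        return float(r), float(c)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    return float((w * rows).sum() / tot), float((w * cols).sum() / tot)


def link(
    detections: list[pd.DataFrame],
    *,
    max_displacement: float,
    pixel_size: float = 1.0,
    frame_interval: float = 0.1,
    memory: int = 3,
    min_length: int = 3,
    y_extent: tuple | None = None,
) -> TrackSet:
    """Greedy nearest-neighbor linking of per-frame detections.

    ``max_displacement`` is the per-frame cap in micrometers; a gap of up to
    ``memory`` frames is bridged (with a proportionally larger cap).  Tracks
    shorter than ``min_length`` detections are removed.  Candidate links are
    assigned in ascending (distance, track id) order, which makes the result
    independent of the detection order within a frame (exact distance ties
    then fall back to detection index).
    """
    next_id = 0
    active: dict[int, tuple[float, float, int]] = {}  # id -> (x, y, last_frame)
    rows = []

    for frame, det in enumerate(detections):
        pts = det[["x_px", "y_px"]].to_numpy() * pixel_size
        assigned_det = set()
        assigned_track = set()
        if len(pts) and active:
            tids = list(active)
            last = np.array([active[i][:2] for i in tids])
            gaps = np.array([frame - active[i][2] for i in tids])
            dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            caps = max_displacement * gaps
            candidates = sorted(
                (dist[a, b], tids[a], b)
                for a in range(len(tids)) for b in range(len(pts))
                if dist[a, b] <= caps[a]
            )
            for d, tid, b in candidates:
                if tid in assigned_track or b in assigned_det:
                    continue
                assigned_track.add(tid)
                assigned_det.add(b)
                active[tid] = (pts[b, 0], pts[b, 1], frame)
                rows.append((tid, frame, pts[b, 0], pts[b, 1]))
        for b in range(len(pts)):
            if b not in assigned_det:
                active[next_id] = (pts[b, 0], pts[b, 1], frame)
                rows.append((next_id, frame, pts[b, 0], pts[b, 1]))
                next_id += 1
        # retire tracks unseen for more than `memory` frames
        stale = [tid for tid, (_, _, f) in active.items()
                 if frame - f >= memory + 1]
        for tid in stale:
            del active[tid]

    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    if y_extent is None:
        y_extent = (float(df["y_um"].min()) if len(df) else 0.0,
                    float(df["y_um"].max()) if len(df) else 1.0)
    ts = TrackSet(df, frame_interval=frame_interval, y_extent=y_extent)
    return ts.filtered(min_length)
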