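"""Rendering of trajectories into synthetic phase-contrast-like movies.

Each cell is drawn as an oriented capsule (rectangle with semicircular
caps) with a ~1 px anti-aliased edge, blurred by a Gaussian point-spread
function and overlaid with additive Gaussian background noise.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.ndimage import gaussian_filter

from ..datatypes import FrameStack, TrajectorySet

__all__ = ["render_frames"]

log = logging.getLogger(__name__)


def _draw_capsule(frame: np.ndarray, x: float, y: float, theta: float,
                  length: float, width: float, pixel_size: float) -> None:
    """Accumulate an anti-aliased capsule of unit intensity into ``frame``."""
    half_seg = max(length - width, 0.0) / 2.0  # half-length of the core segment
    r = width / 2.0
    ux, uy = math.cos(theta), math.sin(theta)
    # bounding box in pixels, padded one pixel for the soft edge
    pad = r + 1.5 * pixel_size
    extent = half_seg * np.array([abs(ux), abs(uy)]) + pad
    c0 = max(int(math.floor((x - extent[0]) / pixel_size)), 0)
    c1 = min(int(math.ceil((x + extent[0]) / pixel_size)), frame.shape[1] - 1)
    r0 = max(int(math.floor((y - extent[1]) / pixel_size)), 0)
    r1 = min(int(math.ceil((y + extent[1]) / pixel_size)), frame.shape[0] - 1)
    if c1 < c0 or r1 < r0:
        return
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    px = cols[None, :] * pixel_size - x
    py = rows[:, None] * pixel_size - y
    # distance to the central segment
    t = np.clip(px * ux + py * uy, -half_seg, half_seg)
    d = np.hypot(px - t * ux, py - t * uy)
    val = np.clip(0.5 + (r - d) / pixel_size, 0.0, 1.0)
    frame[r0:r1 + 1, c0:c1 + 1] += val


def render_frames(traj: TrajectorySet, pixel_size: float, psf_sigma: float = 0.3,
                  noise_sd: float = 0.0, seed: int = 0,
                  shape: tuple[int, int] | None = None) -> FrameStack:
    """Render a trajectory set into a grayscale image stack.

    Parameters
    ----------
    pixel_size : µm per pixel.
    psf_sigma : Gaussian blur sigma in µm (0 disables blurring).
    noise_sd : additive Gaussian background noise, in units of the cell
        peak intensity (cells are drawn at intensity 1).
    shape : output (rows, cols); derived from the arena when omitted.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if shape is None:
        if traj.arena is None:
            raise ValueError("trajectory set has no arena; pass shape explicitly")
        w, h = traj.arena
        shape = (int(math.ceil(h / pixel_size)) + 1, int(math.ceil(w / pixel_size)) + 1)

    widths = traj.data["width_um"].dropna()
    if len(widths) and float(widths.min()) < 2 * pixel_size:
        log.warning(
            "pixel_size %.3g µm resolves the narrowest cell (%.3g µm) with < 2 px; "
            "segmentation accuracy will degrade", pixel_size, float(widths.min()))

    frames_idx = traj.frames
    n_frames = len(frames_idx) if len(frames_idx) else 1
    stack = np.zeros((n_frames, *shape), dtype=np.float64)

    by_frame = dict(tuple(traj.data.groupby("frame"))) if len(traj.data) else {}
    for i, f in enumerate(frames_idx):
        g = by_frame.get(f)
        if g is None:
            continue
        for row in g.itertuples(index=False):
            _draw_capsule(stack[i], row.x_um, row.y_um, row.orientation_rad,
                          row.length_um, row.width_um, pixel_size)

    if psf_sigma > 0:
        sigma_px = psf_sigma / pixel_size
        for i in range(n_frames):
            stack[i] = gaussian_filter(stack[i], sigma_px)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack += rng.normal(0.0, noise_sd, size=stack.shape)

    return FrameStack(frames=stack.astype(np.float32), pixel_size=pixel_size,
                      frame_interval=traj.frame_interval, seed=seed)
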