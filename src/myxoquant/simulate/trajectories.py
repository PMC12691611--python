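"""Agent-based simulation of rod-cell surface motility.

Cells perform a persistent random walk with Poisson-timed 180° reversals,
the canonical kinematic description of twitching *Myxococcus xanthus*
cells.  Per-step speeds are drawn from a normal distribution truncated at
zero whose *truncated* moments are matched to the configured
``speed_mean``/``speed_sd`` (the underlying location/scale are solved for
numerically, so the generated population really has the requested mean and
SD).  An optional trail-following mode deposits a decaying occupancy
raster under every cell and biases headings toward the locally strongest
trail, emulating how secreted exopolysaccharide trails physically
constrain the trajectories of neighbouring cells.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..datatypes import TrajectorySet
from .config import MotilitySimConfig

__all__ = ["simulate_trajectories", "truncated_normal_params"]

# candidate heading offsets scanned when following trails (radians)
_TRAIL_OFFSETS = np.deg2rad([0.0, 20.0, -20.0, 40.0, -40.0, 60.0, -60.0, 80.0, -80.0])


def truncated_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Location/scale of the zero-truncated normal with given truncated moments.

    Solves for (µ, σ) of the underlying normal such that the distribution
    truncated to [0, ∞) has mean ``mean`` and standard deviation ``sd``.
    """
    if sd == 0:
        return mean, 0.0
    if mean <= 0:
        raise ValueError("speed_mean must be > 0 when speed_sd > 0")

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        m, v = stats.truncnorm.stats(-mu / sigma, np.inf, loc=mu, scale=sigma,
                                     moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:  # far from truncation the identity map is exact
        if mean / sd > 4:
            return mean, sd
        raise RuntimeError(f"truncated-normal moment matching failed: {sol.message}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


class _TrailField:
    """Shared decaying occupancy raster deposited under moving cells."""

    def __init__(self, width: float, height: float, resolution: float, decay_time: float,
                 frame_interval: float):
        self.res = resolution
        self.nx = max(2, int(math.ceil(width / resolution)) + 1)
        self.ny = max(2, int(math.ceil(height / resolution)) + 1)
        self.field = np.zeros((self.ny, self.nx))
        self.decay = math.exp(-frame_interval / decay_time)

    def deposit(self, x: np.ndarray, y: np.ndarray) -> None:
        # bilinear deposition of unit mass at each centroid
        gx = np.clip(x / self.res, 0, self.nx - 1 - 1e-9)
        gy = np.clip(y / self.res, 0, self.ny - 1 - 1e-9)
        ix, iy = gx.astype(int), gy.astype(int)
        fx, fy = gx - ix, gy - iy
        np.add.at(self.field, (iy, ix), (1 - fx) * (1 - fy))
        np.add.at(self.field, (iy, ix + 1), fx * (1 - fy))
        np.add.at(self.field, (iy + 1, ix), (1 - fx) * fy)
        np.add.at(self.field, (iy + 1, ix + 1), fx * fy)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        gx = np.clip(x / self.res, 0, self.nx - 1 - 1e-9)
        gy = np.clip(y / self.res, 0, self.ny - 1 - 1e-9)
        ix, iy = gx.astype(int), gy.astype(int)
        fx, fy = gx - ix, gy - iy
        f = self.field
        return (f[iy, ix] * (1 - fx) * (1 - fy) + f[iy, ix + 1] * fx * (1 - fy)
                + f[iy + 1, ix] * (1 - fx) * fy + f[iy + 1, ix + 1] * fx * fy)

    def step_decay(self) -> None:
        self.field *= self.decay


def _wrap_pi(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-π, π]."""
    return np.mod(a + np.pi, 2 * np.pi) - np.pi


def _reflect(pos: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Reflect coordinates into [lo, hi]; returns (position, sign flip)."""
    flip = np.ones_like(pos)
    span = hi - lo
    # fold into a 2*span sawtooth, then mirror the upper half
    p = np.mod(pos - lo, 2 * span)
    over = p > span
    p[over] = 2 * span - p[over]
    flip[over] = -1.0
    return p + lo, flip


def simulate_trajectories(config: MotilitySimConfig) -> TrajectorySet:
    """Simulate ground-truth trajectories for every cell and frame.

    Returns a :class:`TrajectorySet` with provenance ``"ground_truth"``;
    the ``speed_um_min`` column records the realised per-step displacement
    speed (NaN on each track's first frame).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_frames = config.n_frames
    dt = config.frame_interval
    dt_min = dt / 60.0  # frame interval in minutes

    x = rng.uniform(0, config.arena_width, n)
    y = rng.uniform(0, config.arena_height, n)
    heading = rng.uniform(0, 2 * np.pi, n)
    length = np.full(n, config.cell_length_mean)
    width = np.full(n, config.cell_width_mean)
    area = width * (length - width) + np.pi * (width / 2) ** 2  # capsule area

    mu, sigma = truncated_normal_params(config.speed_mean, config.speed_sd)
    turn_sd = (1.0 - config.persistence) * np.pi
    p_reversal = 1.0 - math.exp(-config.reversal_rate * dt)

    trail = None
    if config.trail_following_strength > 0:
        trail = _TrailField(config.arena_width, config.arena_height,
                            resolution=max(config.cell_width_mean, 0.5),
                            decay_time=config.trail_decay_time, frame_interval=dt)

    rows_x = np.empty((n_frames, n))
    rows_y = np.empty((n_frames, n))
    rows_theta = np.empty((n_frames, n))
    rows_speed = np.full((n_frames, n), np.nan)
    rows_x[0], rows_y[0], rows_theta[0] = x, y, heading

    for t in range(1, n_frames):
        if trail is not None:
            trail.deposit(x, y)
            trail.step_decay()

        # persistent random walk update
        heading = heading + rng.normal(0.0, turn_sd, n) if turn_sd > 0 else heading
        if p_reversal > 0:
            heading = np.where(rng.random(n) < p_reversal, heading + np.pi, heading)

        if trail is not None:
            step_ahead = max(config.speed_mean * dt_min, trail.res)
            cand = heading[:, None] + _TRAIL_OFFSETS[None, :]
            cx = x[:, None] + step_ahead * np.cos(cand)
            cy = y[:, None] + step_ahead * np.sin(cand)
            scores = trail.sample(cx.ravel(), cy.ravel()).reshape(n, -1)
            # offsets are ordered by |angle|, so argmax already prefers the
            # smallest turn on ties
            best = np.argmax(scores, axis=1)
            has_trail = scores[np.arange(n), best] > 1e-6
            target = cand[np.arange(n), best]
            delta = _wrap_pi(target - heading)
            heading = np.where(has_trail,
                               heading + config.trail_following_strength * delta,
                               heading)

        if sigma > 0:
            a = (0.0 - mu) / sigma
            speed = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n,
                                        random_state=rng)
        else:
            speed = np.full(n, mu)

        step = speed * dt_min  # µm moved this frame
        x_new = x + step * np.cos(heading)
        y_new = y + step * np.sin(heading)
        x_new, fx = _reflect(x_new, 0.0, config.arena_width)
        y_new, fy = _reflect(y_new, 0.0, config.arena_height)
        # mirror the heading on each reflected axis
        cosh = np.cos(heading) * fx
        sinh = np.sin(heading) * fy
        heading = np.arctan2(sinh, cosh)

        realised = np.hypot(x_new - x, y_new - y) / dt_min  # µm/min
        x, y = x_new, y_new
        rows_x[t], rows_y[t], rows_theta[t] = x, y, heading
        rows_speed[t] = realised

    frames = np.arange(n_frames)
    data = pd.DataFrame(
        {
            "track_id": np.repeat(np.arange(n), n_frames),
            "frame": np.tile(frames, n),
            "x_um": rows_x.T.ravel(),
            "y_um": rows_y.T.ravel(),
            "orientation_rad": np.mod(rows_theta.T.ravel(), np.pi),
            "length_um": np.repeat(length, n_frames),
            "width_um": np.repeat(width, n_frames),
            "area_um2": np.repeat(area, n_frames),
            "speed_um_min": rows_speed.T.ravel(),
            "gap_flag": False,
        }
    )
    return TrajectorySet(
        data=data,
        frame_interval=dt,
        arena=(config.arena_width, config.arena_height),
        provenance="ground_truth",
    )
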