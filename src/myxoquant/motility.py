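"""Surface-exploration statistics computed from trajectories.

The metrics mirror how single-cell twitching-motility movies are usually
summarized: per-step instantaneous velocities pooled into population
distributions, cumulative surface coverage by cell footprints, and
Gaussian-smoothed positional density heatmaps, plus the two-sample
Student's *t* comparison used for velocity populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.ndimage import gaussian_filter

from .datatypes import CoverageMap, DensityHeatmap, TrajectorySet

__all__ = [
    "VelocityProfile",
    "instantaneous_velocities",
    "percent_reduction",
    "student_t_test",
    "cumulative_coverage",
    "density_heatmap",
]

log = logging.getLogger(__name__)


@dataclass
class VelocityProfile:
    """Instantaneous speeds per track and pooled across the population."""

    per_track: dict[int, np.ndarray]
    pooled: np.ndarray  # µm/min
    mean: float
    sd: float
    n_steps: int
    per_track_means: dict[int, float] = field(default_factory=dict)


def instantaneous_velocities(traj: TrajectorySet) -> VelocityProfile:
    """Per-step speeds: Euclidean displacement / frame interval, in µm/min.

    Steps that span gap frames (the arriving detection is gap-flagged or
    consecutive rows are more than one frame apart) are excluded.
    Single-detection tracks contribute no steps and are merely logged.
    """
    dt_min = traj.frame_interval / 60.0
    per_track: dict[int, np.ndarray] = {}
    singletons = 0
    for tid, g in traj.iter_tracks():
        if len(g) < 2:
            singletons += 1
            per_track[tid] = np.array([])
            continue
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        f = g["frame"].to_numpy()
        gap = g["gap_flag"].to_numpy(dtype=bool)
        step = np.hypot(np.diff(x), np.diff(y))
        ok = (np.diff(f) == 1) & ~gap[1:]
        per_track[tid] = step[ok] / dt_min
    if singletons:
        log.info("%d single-detection tracks contributed no velocity steps", singletons)

    pooled = (np.concatenate([v for v in per_track.values()])
              if per_track else np.array([]))
    mean = float(pooled.mean()) if pooled.size else 0.0
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    means = {tid: (float(v.mean()) if v.size else np.nan) for tid, v in per_track.items()}
    return VelocityProfile(per_track=per_track, pooled=pooled, mean=mean, sd=sd,
                           n_steps=int(pooled.size), per_track_means=means)


def percent_reduction(reference_mean: float, test_mean: float) -> float:
    """Percent decrease of ``test_mean`` relative to ``reference_mean``.

    Returned rounded to two decimals, matching how such reductions are
    conventionally reported.
    """
    if reference_mean <= 0:
        raise ValueError("reference_mean must be > 0")
    return round(100.0 * (reference_mean - test_mean) / reference_mean, 2)


def student_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample pooled-variance (Student's) t test, two-sided.

    Degenerate zero-variance inputs follow the convention: equal means →
    ``(0, 1)``; unequal means with zero pooled variance → ``(±inf, 0)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sstats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def cumulative_coverage(traj: TrajectorySet,
                        arena: tuple[float, float] | None = None,
                        grid_pixel_size: float = 0.5,
                        full_width_radius: bool = False) -> CoverageMap:
    """Union of per-detection disc footprints accumulated over time.

    Each detection stamps a disc at its centroid with radius equal to the
    cell's minor *semi*-axis (half the short-axis width); with
    ``full_width_radius=True`` the full short-axis length is used as the
    radius instead.  A grid pixel belongs to a disc when its centre lies
    within the disc radius.  Per-frame cumulative covered fractions are
    recorded alongside the final raster.
    """
    if arena is None:
        arena = traj.arena
    if arena is None:
        raise ValueError("arena bounds required (none carried by the trajectory set)")
    if grid_pixel_size <= 0:
        raise ValueError("grid_pixel_size must be > 0")
    w, h = arena
    nx = int(np.ceil(w / grid_pixel_size)) + 1
    ny = int(np.ceil(h / grid_pixel_size)) + 1
    raster = np.zeros((ny, nx), dtype=bool)

    widths = traj.data["width_um"].dropna()
    if len(widths):
        min_r = float(widths.min()) * (1.0 if full_width_radius else 0.5)
        if grid_pixel_size > min_r:
            log.warning("grid pixel (%.3g µm) exceeds the smallest footprint radius "
                        "(%.3g µm); coverage will be quantization-limited",
                        grid_pixel_size, min_r)

    frames = traj.frames
    fractions = np.zeros(len(frames))
    by_frame = dict(tuple(traj.data.groupby("frame"))) if len(traj.data) else {}
    for i, f in enumerate(frames):
        g = by_frame.get(f)
        if g is not None:
            for row in g.itertuples(index=False):
                r = row.width_um * (1.0 if full_width_radius else 0.5)
                if not np.isfinite(r) or r <= 0:
                    continue
                _stamp_disc(raster, row.x_um, row.y_um, r, grid_pixel_size)
        fractions[i] = raster.sum() / raster.size

    frac = float(raster.sum() / raster.size)
    return CoverageMap(raster=raster, grid_pixel_size=grid_pixel_size,
                       coverage_fraction=frac, per_frame_fractions=fractions)


def _stamp_disc(raster: np.ndarray, x: float, y: float, r: float, px: float) -> None:
    """Mark pixels whose centres fall within radius r of (x, y), in µm."""
    c0 = max(int(np.floor((x - r) / px)), 0)
    c1 = min(int(np.ceil((x + r) / px)), raster.shape[1] - 1)
    r0 = max(int(np.floor((y - r) / px)), 0)
    r1 = min(int(np.ceil((y + r) / px)), raster.shape[0] - 1)
    if c1 < c0 or r1 < r0:
        return
    cols = np.arange(c0, c1 + 1) * px - x
    rows = np.arange(r0, r1 + 1) * px - y
    inside = rows[:, None] ** 2 + cols[None, :] ** 2 <= r * r
    raster[r0:r1 + 1, c0:c1 + 1] |= inside


def density_heatmap(points: np.ndarray, bin_size: float, sigma: float,
                    extent: tuple[float, float, float, float] | None = None
                    ) -> DensityHeatmap:
    """Gaussian-smoothed 2-D histogram of cell-centre coordinates.

    ``points`` is (N, 2) as (x, y) in µm.  Smoothing uses reflect padding,
    which conserves total mass: the array sum equals the number of points.
    ``sigma`` is in µm (0 disables smoothing).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if extent is None:
        if pts.size:
            x0, y0 = pts.min(axis=0)
            x1, y1 = pts.max(axis=0)
        else:
            x0 = y0 = 0.0
            x1 = y1 = bin_size
        extent = (x0, x1 + 1e-9, y0, y1 + 1e-9)
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / bin_size)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_size)), 1)
    hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=(ny, nx),
                                range=((y0, y0 + ny * bin_size),
                                       (x0, x0 + nx * bin_size)))
    if sigma > 0:
        hist = gaussian_filter(hist, sigma / bin_size, mode="reflect")
    return DensityHeatmap(density=hist, bin_size=bin_size, sigma=sigma,
                          extent=(x0, x1, y0, y1))
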