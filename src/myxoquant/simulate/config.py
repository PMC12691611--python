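"""Configuration dataclasses for the synthetic-data generators.

Every config validates its physical invariants on construction and raises
``ValueError`` naming the offending field.  Identical config + seed pairs
produce bit-identical outputs from every generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

__all__ = ["MotilitySimConfig", "ColocSimConfig", "SPRSimConfig", "ITCSimConfig"]


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass
class MotilitySimConfig:
    """Parameters of the agent-based rod-cell motility simulation.

    Defaults reproduce the standard single-cell motility assay regime:
    cells filmed for 1,000 s at 10 s intervals, moving at a few to a dozen
    µm/min by a persistent random walk with occasional reversals, with an
    optional bias of headings toward a shared, decaying extracellular
    trail field.
    """

    arena_width: float = 200.0  # µm
    arena_height: float = 200.0  # µm
    pixel_size: float = 0.2  # µm/px (used when rendering frames)
    n_cells: int = 20
    duration: float = 1000.0  # s
    frame_interval: float = 10.0  # s
    speed_mean: float = 10.36  # µm/min
    speed_sd: float = 5.03  # µm/min
    persistence: float = 0.9  # 0 = fresh heading each step, 1 = straight
    reversal_rate: float = 0.005  # 180° flips per second
    trail_following_strength: float = 0.0  # 0 = ignore trails, 1 = lock on
    trail_decay_time: float = 500.0  # s, e-folding time of deposited trails
    cell_length_mean: float = 5.0  # µm
    cell_width_mean: float = 0.8  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arena_width", "arena_height", "pixel_size", "cell_length_mean",
                     "cell_width_mean", "trail_decay_time"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.n_cells >= 0, "n_cells must be ≥ 0")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.duration >= self.frame_interval, "duration must be ≥ frame_interval")
        _require(self.speed_mean >= 0, "speed_mean must be ≥ 0")
        _require(self.speed_sd >= 0, "speed_sd must be ≥ 0")
        _require(0.0 <= self.persistence <= 1.0, "persistence must lie in [0, 1]")
        _require(self.reversal_rate >= 0, "reversal_rate must be ≥ 0")
        _require(0.0 <= self.trail_following_strength <= 1.0,
                 "trail_following_strength must lie in [0, 1]")
        _require(self.cell_width_mean <= self.cell_length_mean,
                 "cell_width_mean must be ≤ cell_length_mean")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration / self.frame_interval)) + 1


@dataclass
class ColocSimConfig:
    """Two-channel object-placement model for colocalization tests.

    A fraction ``overlap_fraction`` of the second channel's objects are
    centred on first-channel objects; the rest are placed independently.
    """

    shape: tuple[int, int] = (256, 256)  # (rows, cols) px
    n_objects: int = 50  # per channel
    overlap_fraction: float = 0.5
    object_radius: float = 3.0  # px
    intensity_r: float = 100.0
    intensity_g: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.shape) == 2 and min(self.shape) > 0, "shape must be 2-D positive")
        _require(self.n_objects >= 0, "n_objects must be ≥ 0")
        _require(0.0 <= self.overlap_fraction <= 1.0, "overlap_fraction must lie in [0, 1]")
        _require(self.object_radius > 0, "object_radius must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be ≥ 0")


@dataclass
class SPRSimConfig:
    """Steady-state 1:1 Langmuir response generator parameters."""

    Rmax: float = 100.0  # RU
    K_D: float = 1e-4  # M
    concentrations: Sequence[float] = field(
        default_factory=lambda: [31.25e-6, 62.5e-6, 125e-6, 250e-6, 500e-6, 1000e-6]
    )
    noise_sd: float = 0.0  # RU
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.Rmax > 0, "Rmax must be > 0")
        _require(self.K_D > 0, "K_D must be > 0")
        conc = np.asarray(list(self.concentrations), dtype=float)
        _require(conc.size > 0 and np.all(conc > 0), "concentrations must all be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be ≥ 0")
        self.concentrations = conc


@dataclass
class ITCSimConfig:
    """One-set-of-sites titration generator parameters.

    The default geometry is a 300 µL sample cell receiving 19 sequential
    2 µL injections.  ``dilution_heat`` is a constant per-mole offset
    emulating the heat of mixing that a buffer-only control titration
    would measure.
    """

    n: float = 1.0  # stoichiometry, sites per macromolecule
    K_D: float = 1e-4  # M
    dH: float = -5.0  # kcal/mol of injectant
    cell_volume: float = 300.0  # µL
    injection_volume: float = 2.0  # µL
    n_injections: int = 19
    cell_conc: float = 1e-3  # M macromolecule in the cell
    syringe_conc: float = 2e-2  # M ligand stock
    dilution_heat: float = 0.0  # kcal/mol offset
    noise_sd: float = 0.0  # kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n", "K_D", "cell_volume", "injection_volume", "cell_conc",
                     "syringe_conc"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.n_injections >= 1, "n_injections must be ≥ 1")
        _require(self.noise_sd >= 0, "noise_sd must be ≥ 0")


def config_to_dict(cfg) -> dict:
    """Plain-dict view of any sim config (for provenance records)."""
    out = {}
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out
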