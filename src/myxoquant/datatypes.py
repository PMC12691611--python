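"""Core data containers shared across the pipeline.

All public spatial quantities are expressed in micrometres (µm), times in
seconds, and speeds in µm/min.  Image coordinates follow the microscopy
convention: origin at the top-left pixel centre, ``x`` is the column index
and ``y`` the row index, both increasing right/down.  Orientations are
axial (a rod has indistinguishable ends) and reduced modulo π to [0, π).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TRACK_COLUMNS",
    "TrajectorySet",
    "FrameStack",
    "ChannelPair",
    "SPRDataset",
    "ITCDataset",
    "CoverageMap",
    "DensityHeatmap",
]

#: canonical column order of trajectory tables (CSV and in-memory)
TRACK_COLUMNS = [
    "track_id",
    "frame",
    "x_um",
    "y_um",
    "orientation_rad",
    "length_um",
    "width_um",
    "area_um2",
    "speed_um_min",
    "gap_flag",
]


@dataclass
class TrajectorySet:
    """Per-cell, per-frame positions and morphology.

    The common currency between the simulator, the tracker and the metrics
    layer.  ``data`` is a tidy table with one row per (track, frame); see
    :data:`TRACK_COLUMNS`.  ``provenance`` distinguishes simulator ground
    truth (``"ground_truth"``) from inferred tracks (``"tracked"``).
    """

    data: pd.DataFrame
    frame_interval: float  # s
    arena: Optional[tuple[float, float]] = None  # (width, height) µm
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        for col in ("track_id", "frame", "x_um", "y_um"):
            if col not in self.data.columns:
                raise ValueError(f"trajectory table missing column {col!r}")
        for col in TRACK_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan if col != "gap_flag" else False
        self.data = self.data[TRACK_COLUMNS].reset_index(drop=True)
        # frame indices must strictly increase within each track
        for tid, g in self.data.groupby("track_id"):
            f = g["frame"].to_numpy()
            if np.any(np.diff(f) <= 0):
                raise ValueError(f"track {tid}: frame indices not strictly increasing")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.data["frame"].unique())

    def iter_tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        for tid, g in self.data.groupby("track_id", sort=True):
            yield tid, g.sort_values("frame")

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["provenance"] = self.provenance
        out["frame_interval_s"] = self.frame_interval
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectorySet":
        df = pd.read_csv(path)
        provenance = "ground_truth"
        if "provenance" in df.columns and len(df):
            provenance = str(df["provenance"].iloc[0])
        if "frame_interval_s" in df.columns and len(df):
            dt = float(df["frame_interval_s"].iloc[0])
        else:
            raise ValueError(f"{path}: no frame_interval_s column")
        df = df.drop(columns=[c for c in ("provenance", "frame_interval_s") if c in df.columns])
        return cls(data=df, frame_interval=dt, provenance=provenance)


@dataclass
class FrameStack:
    """Time-ordered grayscale images with physical metadata."""

    frames: np.ndarray  # (T, H, W) float
    pixel_size: float  # µm/px
    frame_interval: float  # s
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ChannelPair:
    """Two co-registered intensity images plus thresholds for colocalization.

    ``t_r``/``t_g`` left as ``None`` request automatic (Otsu) thresholds
    when a Manders coefficient is computed.
    """

    channel_r: np.ndarray
    channel_g: np.ndarray
    mask: Optional[np.ndarray] = None
    t_r: Optional[float] = None
    t_g: Optional[float] = None

    def __post_init__(self) -> None:
        self.channel_r = np.asarray(self.channel_r, dtype=float)
        self.channel_g = np.asarray(self.channel_g, dtype=float)
        if self.channel_r.shape != self.channel_g.shape:
            raise ValueError("channel shapes differ")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.channel_r.shape:
                raise ValueError("mask shape differs from channels")
        for name, t in (("t_r", self.t_r), ("t_g", self.t_g)):
            if t is not None and t < 0:
                raise ValueError(f"{name} must be ≥ 0")

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened channel values restricted to the analysis mask."""
        if self.mask is None:
            return self.channel_r.ravel(), self.channel_g.ravel()
        return self.channel_r[self.mask], self.channel_g[self.mask]


@dataclass
class SPRDataset:
    """Steady-state SPR equilibrium responses.

    One row per analyte concentration; responses in resonance units (RU).
    """

    concentration_M: np.ndarray
    response_RU: np.ndarray
    ligand: str = ""
    analyte: str = ""
    pH: Optional[float] = None

    def __post_init__(self) -> None:
        self.concentration_M = np.asarray(self.concentration_M, dtype=float)
        self.response_RU = np.asarray(self.response_RU, dtype=float)
        if self.concentration_M.shape != self.response_RU.shape:
            raise ValueError("concentration and response lengths differ")
        if np.any(self.concentration_M <= 0):
            raise ValueError("concentrations must be > 0")
        if len(np.unique(self.concentration_M)) != len(self.concentration_M):
            raise ValueError("concentrations must be unique")

    def __len__(self) -> int:
        return len(self.concentration_M)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"concentration_M": self.concentration_M, "response_RU": self.response_RU}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "SPRDataset":
        df = pd.read_csv(path)
        return cls(df["concentration_M"].to_numpy(), df["response_RU"].to_numpy(), **meta)


@dataclass
class ITCDataset:
    """Per-injection normalized heats with the instrument geometry.

    Heats are kcal per mole of injectant.  ``control_heats``, when present,
    is the matching buffer-only (dilution) titration.
    """

    heats_kcal_mol: np.ndarray
    cell_volume_uL: float
    injection_volumes_uL: np.ndarray
    cell_conc_M: float
    syringe_conc_M: float
    control_heats_kcal_mol: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.heats_kcal_mol = np.asarray(self.heats_kcal_mol, dtype=float)
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        if self.heats_kcal_mol.shape != self.injection_volumes_uL.shape:
            raise ValueError("heats and injection volumes lengths differ")
        if self.cell_volume_uL <= 0 or self.cell_conc_M <= 0 or self.syringe_conc_M <= 0:
            raise ValueError("cell volume and concentrations must be > 0")
        if np.any(self.injection_volumes_uL <= 0):
            raise ValueError("injection volumes must be > 0")
        if not np.all(np.isfinite(self.heats_kcal_mol)):
            raise ValueError("heats must be finite")
        if self.control_heats_kcal_mol is not None:
            self.control_heats_kcal_mol = np.asarray(self.control_heats_kcal_mol, dtype=float)
            if self.control_heats_kcal_mol.shape != self.heats_kcal_mol.shape:
                raise ValueError("control series length differs from data")

    @property
    def n_injections(self) -> int:
        return len(self.heats_kcal_mol)

    def molar_ratios(self) -> np.ndarray:
        """Ligand:macromolecule molar ratio in the cell after each injection."""
        from .binding import itc_cell_concentrations

        mt, xt = itc_cell_concentrations(
            self.cell_conc_M,
            self.syringe_conc_M,
            self.cell_volume_uL,
            self.injection_volumes_uL,
        )
        return xt / mt

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "injection": np.arange(1, self.n_injections + 1),
                "injection_volume_uL": self.injection_volumes_uL,
                "heat_kcal_mol": self.heats_kcal_mol,
            }
        )
        if self.control_heats_kcal_mol is not None:
            df["control_heat_kcal_mol"] = self.control_heats_kcal_mol
        df["cell_volume_uL"] = self.cell_volume_uL
        df["cell_conc_M"] = self.cell_conc_M
        df["syringe_conc_M"] = self.syringe_conc_M
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ITCDataset":
        df = pd.read_csv(path)
        control = None
        if "control_heat_kcal_mol" in df.columns:
            control = df["control_heat_kcal_mol"].to_numpy()
        return cls(
            heats_kcal_mol=df["heat_kcal_mol"].to_numpy(),
            cell_volume_uL=float(df["cell_volume_uL"].iloc[0]),
            injection_volumes_uL=df["injection_volume_uL"].to_numpy(),
            cell_conc_M=float(df["cell_conc_M"].iloc[0]),
            syringe_conc_M=float(df["syringe_conc_M"].iloc[0]),
            control_heats_kcal_mol=control,
        )


@dataclass
class CoverageMap:
    """Boolean raster of arena area visited by cell footprints."""

    raster: np.ndarray  # bool (H, W)
    grid_pixel_size: float  # µm/px
    coverage_fraction: float
    per_frame_fractions: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        f = np.asarray(self.per_frame_fractions, dtype=float)
        if f.size and np.any(np.diff(f) < -1e-12):
            raise ValueError("cumulative coverage fractions must be non-decreasing")
        self.per_frame_fractions = f


@dataclass
class DensityHeatmap:
    """Gaussian-smoothed 2-D histogram of cell-centre coordinates."""

    density: np.ndarray
    bin_size: float  # µm
    sigma: float  # µm
    extent: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)  # x0, x1, y0, y1 µm
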