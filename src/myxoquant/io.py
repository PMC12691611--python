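"""Reading and writing of movies, rasters and tabular datasets."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import FrameStack

__all__ = ["write_stack", "read_stack", "write_raster_png"]


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus a ``.json`` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "seed": stack.seed,
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    return FrameStack(frames=frames, pixel_size=float(meta["pixel_size_um"]),
                      frame_interval=float(meta["frame_interval_s"]),
                      seed=meta.get("seed"))


def write_raster_png(raster: np.ndarray, path: str | Path,
                     cmap: str = "viridis") -> None:
    """Render a 2-D array (boolean or float) to a PNG via matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    ax.imshow(np.asarray(raster, dtype=float), cmap=cmap, origin="upper")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
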