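"""Colocalization statistics for two-channel fluorescence images.

Four standard measures of spatial correspondence between a red and a
green/blue channel:

* **PCC** — Pearson's correlation coefficient of pixel intensities,
  −1 (perfect anti-correlation) to +1 (perfect correlation).
* **M1 / M2** — Manders overlap coefficients: the fraction of channel-R
  intensity on pixels where channel G exceeds its threshold, and vice
  versa; each in [0, 1].
* **ICQ** — intensity correlation quotient: the fraction of pixels whose
  intensities deviate from the channel means with the same sign, minus
  0.5; −0.5 (complete segregation) to +0.5 (complete colocalization).
  Pixels with a zero mean-deviation product are excluded, which makes the
  ±0.5 limiting cases exact.

All statistics honour an optional analysis mask; Manders thresholds
default to per-channel Otsu when not supplied on the :class:`ChannelPair`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .datatypes import ChannelPair

__all__ = ["ColocResult", "pearson_cc", "manders", "icq", "coloc_stats"]


@dataclass
class ColocResult:
    """The four colocalization statistics over the analysed pixels."""

    M1: float
    M2: float
    PCC: float
    ICQ: float
    n_pixels: int

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (-eps <= self.M1 <= 1 + eps and -eps <= self.M2 <= 1 + eps):
            raise ValueError("M1/M2 out of [0, 1]")
        if not (-1 - eps <= self.PCC <= 1 + eps):
            raise ValueError("PCC out of [-1, 1]")
        if not (-0.5 - eps <= self.ICQ <= 0.5 + eps):
            raise ValueError("ICQ out of [-0.5, 0.5]")


def pearson_cc(pair: ChannelPair) -> float:
    """Pearson's correlation coefficient over the masked pixels."""
    r, g = pair.masked()
    if r.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(r) == 0 or np.ptp(g) == 0:
        raise ValueError("PCC undefined: a channel is constant over the mask")
    rc = r - r.mean()
    gc = g - g.mean()
    denom = np.sqrt(np.dot(rc, rc) * np.dot(gc, gc))
    if denom == 0:  # numerically constant channel
        raise ValueError("PCC undefined: a channel is constant over the mask")
    return float(np.dot(rc, gc) / denom)


def _thresholds(pair: ChannelPair) -> tuple[float, float]:
    r, g = pair.masked()
    t_r = pair.t_r if pair.t_r is not None else float(threshold_otsu(r))
    t_g = pair.t_g if pair.t_g is not None else float(threshold_otsu(g))
    return t_r, t_g


def manders(pair: ChannelPair) -> tuple[float, float]:
    """Manders overlap coefficients (M1, M2).

    M1 = Σ R over pixels with G > t_g, divided by Σ R; M2 symmetrically
    with the channels swapped.  Thresholds default to per-channel Otsu.
    """
    r, g = pair.masked()
    if r.sum() <= 0 or g.sum() <= 0:
        raise ValueError("Manders coefficients undefined: a channel sums to zero")
    t_r, t_g = _thresholds(pair)
    m1 = float(r[g > t_g].sum() / r.sum())
    m2 = float(g[r > t_r].sum() / g.sum())
    return m1, m2


def icq(pair: ChannelPair) -> float:
    """Intensity correlation quotient over the masked pixels."""
    r, g = pair.masked()
    if np.ptp(r) == 0 or np.ptp(g) == 0:
        raise ValueError("ICQ undefined: a channel is constant over the mask")
    prod = (r - r.mean()) * (g - g.mean())
    nz = prod[prod != 0]
    if nz.size == 0:
        raise ValueError("ICQ undefined: all mean-deviation products are zero")
    return float((nz > 0).mean() - 0.5)


def coloc_stats(pair: ChannelPair) -> ColocResult:
    """All four statistics in one pass (shared thresholds and mask)."""
    m1, m2 = manders(pair)
    r, _ = pair.masked()
    return ColocResult(M1=m1, M2=m2, PCC=pearson_cc(pair), ICQ=icq(pair),
                       n_pixels=int(r.size))
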