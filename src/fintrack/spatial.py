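"""Positional occupancy heatmaps and dwell fractions in labeled zones.

The occupancy heatmap counts how often any fish was recorded in each
pixel (or square bin) of the tank view over a clip set; comparing the
exposed and control groups' heatmaps reveals spatial preference, e.g.
dwelling at the tank center under a static magnetic field whose high
field strengths form a concentric ring. Field geometry is supplied as
configuration — named annular zones with optional field-strength labels
in mT — not computed from magnet physics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .track import Track

logger = logging.getLogger(__name__)


@dataclass
class Heatmap:
    """Dwell counts over a square-binned pixel grid.

    counts[row, col] is the number of recorded positions whose pixel
    falls in that bin; bin (r, c) covers pixels
    [c*b, (c+1)*b) x [r*b, (r+1)*b) for bin size b.
    """

    counts: np.ndarray
    bin_size_px: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if self.bin_size_px < 1:
            raise ValueError("bin_size_px must be a positive integer")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) pixel coordinates of every bin center, each shaped
        like ``counts`` (pixel centers at integers)."""
        b = self.bin_size_px
        rows, cols = np.indices(self.counts.shape)
        return cols * b + (b - 1) / 2.0, rows * b + (b - 1) / 2.0


@dataclass(frozen=True)
class Zone:
    """Named annulus (r_inner <= distance < r_outer from its center)."""

    name: str
    center_x: float
    center_y: float
    r_inner_px: float
    r_outer_px: float
    field_mT: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.r_inner_px < self.r_outer_px:
            raise ValueError(f"zone {self.name!r}: need 0 <= r_inner < r_outer")

    def contains(self, x, y):
        d = np.hypot(np.asarray(x) - self.center_x, np.asarray(y) - self.center_y)
        return (d >= self.r_inner_px) & (d < self.r_outer_px)


def build_heatmap(
    tracks: Sequence[Track] | Sequence[np.ndarray],
    frame_shape: tuple[int, int],
    bin_size_px: int = 1,
    include_coasted: bool = True,
) -> Heatmap:
    """Accumulate per-frame positions of all tracks into a dwell-count grid.

    ``frame_shape`` is (height_px, width_px). Each position increments
    the bin containing its pixel (floor of coordinate / bin size);
    coasted positions are included unless ``include_coasted`` is False.
    The counts always sum to the number of recorded positions.
    """
    if not len(tracks):
        raise ValueError("no tracks")
    h, w = frame_shape
    if h < 1 or w < 1:
        raise ValueError("frame_shape must be positive")
    n_rows = math.ceil(h / bin_size_px)
    n_cols = math.ceil(w / bin_size_px)
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    for tr in tracks:
        if isinstance(tr, Track):
            pos = tr.positions
            keep = tr.observed if not include_coasted else np.ones(tr.n_frames, bool)
        else:
            pos = np.asarray(tr, dtype=np.float64).reshape(-1, 2)
            keep = np.ones(pos.shape[0], bool)
        pos = pos[keep]
        cols = np.clip(np.floor(pos[:, 0] / bin_size_px).astype(int), 0, n_cols - 1)
        rows = np.clip(np.floor(pos[:, 1] / bin_size_px).astype(int), 0, n_rows - 1)
        np.add.at(counts, (rows, cols), 1)
    logger.info(
        "heatmap %dx%d bins (bin %d px), %d positions",
        n_rows, n_cols, bin_size_px, int(counts.sum()),
    )
    return Heatmap(counts=counts, bin_size_px=bin_size_px)


def zone_occupancy(heatmap: Heatmap, zones: Sequence[Zone]) -> dict[str, float]:
    """Fraction of recorded positions dwelling in each zone.

    A bin belongs to the zone containing its center point; bins in no
    zone fall in the implicit ``outside`` zone. Fractions over
    {zones..., outside} sum to 1. Overlapping zones are reported with a
    warning; a bin in several zones counts toward the first that
    contains it.
    """
    names = [z.name for z in zones]
    if len(set(names)) != len(names):
        raise ValueError("zone names must be unique")
    total = heatmap.total
    if total == 0:
        raise ValueError("heatmap is empty")
    cx, cy = heatmap.bin_centers()
    membership = np.stack([z.contains(cx, cy) for z in zones]) if zones else np.zeros(
        (0,) + heatmap.counts.shape, dtype=bool
    )
    if len(zones) > 1 and (membership.sum(axis=0) > 1).any():
        warnings.warn("zones overlap; bins count toward the first containing zone",
                      stacklevel=2)
    taken = np.zeros(heatmap.counts.shape, dtype=bool)
    fractions: dict[str, float] = {}
    for z, member in zip(zones, membership):
        mine = member & ~taken
        taken |= member
        fractions[z.name] = float(heatmap.counts[mine].sum()) / total
    fractions["outside"] = float(heatmap.counts[~taken].sum()) / total
    return fractions
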