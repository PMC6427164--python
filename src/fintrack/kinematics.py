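"""Per-clip path length and average swimming velocity.

A clip's total swimming distance is the superposition of Euclidean
distances between the fish position in consecutive frames,

    D = sum_{i=2..n_c} sqrt((s_x,i - s_x,i-1)^2 + (s_y,i - s_y,i-1)^2),

where n_c is the number of frames in the clip. Two normalizations are
reported: per frame transition, D / (n_c - 1) — the natural denominator
for a sum over i = 2..n_c, and the unit of published per-clip velocity
tables — and per second, D / clip duration (default 300 s, the 5-minute
clip length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .track import Track

#: default clip duration in seconds (5-minute clips)
DEFAULT_CLIP_DURATION_S = 300.0


@dataclass(frozen=True)
class ClipVelocity:
    """Average swimming speed of one fish over one clip."""

    clip_id: str
    n_c: int  # total number of frames
    total_distance_px: float
    velocity_px_per_frame: float  # total_distance_px / (n_c - 1)
    velocity_px_per_s: float  # total_distance_px / clip duration


def clip_velocity(
    track: Track | np.ndarray,
    clip_duration_s: float = DEFAULT_CLIP_DURATION_S,
    clip_id: str = "",
) -> ClipVelocity:
    """Total path length and average velocity of one track.

    Accepts a :class:`~fintrack.track.Track` or a bare (n_frames, 2)
    position array. Coasted frames repeat the last position and so
    contribute zero distance.
    """
    positions = track.positions if isinstance(track, Track) else np.asarray(track, float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n_frames, 2)")
    n_c = positions.shape[0]
    if n_c < 2:
        raise ValueError(f"need at least 2 frames, got {n_c}")
    if clip_duration_s <= 0:
        raise ValueError("clip_duration_s must be positive")
    steps = np.diff(positions, axis=0)
    total = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    return ClipVelocity(
        clip_id=clip_id,
        n_c=n_c,
        total_distance_px=total,
        velocity_px_per_frame=total / (n_c - 1),
        velocity_px_per_s=total / clip_duration_s,
    )


def _velocities(clips: Sequence) -> list[float]:
    out = []
    for c in clips:
        out.append(c.velocity_px_per_frame if isinstance(c, ClipVelocity) else float(c))
    return out


def group_means(groups: Mapping[str, Sequence]) -> dict[str, float]:
    """Arithmetic mean per-clip velocity of each group."""
    means = {}
    for name, clips in groups.items():
        v = _velocities(clips)
        if not v:
            raise ValueError(f"group {name!r} is empty")
        means[name] = float(np.mean(v))
    return means


def group_velocity_table(groups: Mapping[str, Sequence]) -> pd.DataFrame:
    """Per-group sorted velocity columns with a trailing ``Average`` row.

    Accepts per group either :class:`ClipVelocity` objects or bare
    velocities; each column is sorted ascending (the layout of published
    per-clip velocity tables, where rows pair clips by velocity rank).
    Groups may have different sizes; shorter columns are NaN-padded
    before the Average row, and each Average is over that group's own
    clips.
    """
    means = group_means(groups)
    cols = {name: sorted(_velocities(clips)) for name, clips in groups.items()}
    n = max(len(v) for v in cols.values())
    data = {
        name: v + [math.nan] * (n - len(v)) for name, v in cols.items()
    }
    table = pd.DataFrame(data, index=pd.Index(range(1, n + 1), name="clip"))
    table.loc["Average"] = [means[name] for name in table.columns]
    return table
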