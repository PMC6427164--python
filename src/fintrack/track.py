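"""Frame-to-frame identity resolution by shortest-Euclidean-distance mapping.

Detections in consecutive frames are associated by the injective
matching that minimizes the total Euclidean distance between previous
track positions and current detections, among all matchings of maximal
size whose pairs lie within a distance gate. This is the optimal
(Hungarian) assignment; a greedy per-track nearest-neighbor mode is
available for comparison. Tracks that miss a detection coast — they
hold their last known position (flagged unobserved) so every track has
exactly one position per frame and path-length sums stay well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .detect import Detection

logger = logging.getLogger(__name__)

#: default association gate in pixels; large relative to realistic
#: per-frame fish displacements (a few px/frame) so only teleporting
#: matches after occlusion are rejected
DEFAULT_MAX_GATE_PX = 50.0

# lexicographic tie-break perturbation; far below any meaningful
# distance difference, far above float64 rounding of pixel-scale costs
_TIE_EPS = 1e-9


class TrackInitializationError(RuntimeError):
    """No frame ever contained enough detections to start the tracks."""


@dataclass
class Track:
    """One fish identity: a position per frame plus observed/coasted flags."""

    fish_id: int
    positions: np.ndarray  # (n_frames, 2) float (x, y)
    observed: np.ndarray  # (n_frames,) bool; False where the track coasted

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_frames, 2)")
        if self.observed.shape != (self.positions.shape[0],):
            raise ValueError("observed must have one flag per frame")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class AssignmentResult:
    """Detection index per track (None = unmatched) and total matched cost."""

    mapping: tuple
    total_cost: float


def _detection_xy(detections) -> np.ndarray:
    if len(detections) == 0:
        return np.zeros((0, 2))
    if isinstance(detections[0], Detection):
        return np.array([[d.centroid_x, d.centroid_y] for d in detections])
    return np.asarray(detections, dtype=np.float64).reshape(len(detections), 2)


def assign(
    prev_positions,
    detections,
    max_gate_px: float = DEFAULT_MAX_GATE_PX,
    method: str = "optimal",
) -> AssignmentResult:
    """Associate detections to previous positions.

    ``optimal`` returns the injective matching minimizing total
    Euclidean distance among all matchings of maximal size with every
    matched pair within ``max_gate_px``; ties are broken toward the
    lexicographically smallest (track index, detection index) mapping.
    ``greedy`` lets each track in order claim its nearest unclaimed
    detection within the gate.
    """
    prev = np.asarray(prev_positions, dtype=np.float64).reshape(-1, 2)
    det_xy = _detection_xy(detections)
    n, m = prev.shape[0], det_xy.shape[0]
    if n == 0 or m == 0:
        return AssignmentResult(mapping=(None,) * n, total_cost=0.0)
    dist = cdist(prev, det_xy)
    if method == "greedy":
        return _assign_greedy(dist, max_gate_px)
    if method != "optimal":
        raise ValueError(f"unknown assignment method {method!r}")
    # one forbidden (out-of-gate) assignment costs more than any entire
    # feasible matching, so the solver maximizes matching size first,
    # then minimizes true cost
    big = min(n, m) * max_gate_px + 1.0
    cost = np.where(dist <= max_gate_px, dist, big)
    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    cost = cost + _TIE_EPS * (i_idx * m + j_idx)
    rows, cols = linear_sum_assignment(cost)
    mapping: list = [None] * n
    total = 0.0
    for r, c in zip(rows, cols):
        if dist[r, c] <= max_gate_px:
            mapping[r] = int(c)
            total += float(dist[r, c])
    return AssignmentResult(mapping=tuple(mapping), total_cost=total)


def _assign_greedy(dist: np.ndarray, max_gate_px: float) -> AssignmentResult:
    n, m = dist.shape
    mapping: list = [None] * n
    claimed = np.zeros(m, dtype=bool)
    total = 0.0
    for i in range(n):
        d = np.where(claimed, np.inf, dist[i])
        j = int(np.argmin(d))
        if d[j] <= max_gate_px:
            mapping[i] = j
            claimed[j] = True
            total += float(dist[i, j])
    return AssignmentResult(mapping=tuple(mapping), total_cost=total)


def build_tracks(
    detections_by_frame: Sequence[Sequence],
    n_fish: int,
    max_gate_px: float = DEFAULT_MAX_GATE_PX,
    method: str = "optimal",
) -> list[Track]:
    """Build per-fish tracks over a clip from per-frame detections.

    Tracks initialize at the first frame holding at least ``n_fish``
    detections (taking the first ``n_fish`` in their sorted order) and
    are backfilled to frame 0 as coasted. From there, :func:`assign`
    links frame to frame; unmatched tracks coast, surplus detections
    are ignored. Matches close to the gate are logged as swap suspects.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    n_frames = len(detections_by_frame)
    if n_frames == 0:
        raise ValueError("no frames")
    start = next(
        (t for t, dets in enumerate(detections_by_frame) if len(dets) >= n_fish),
        None,
    )
    if start is None:
        raise TrackInitializationError(
            f"no frame contains {n_fish} detections; tracking cannot initialize"
        )
    positions = np.zeros((n_fish, n_frames, 2))
    observed = np.zeros((n_fish, n_frames), dtype=bool)
    init_xy = _detection_xy(detections_by_frame[start])[:n_fish]
    positions[:, : start + 1] = init_xy[:, None, :]
    observed[:, start] = True

    n_suspects = 0
    for t in range(start + 1, n_frames):
        det_xy = _detection_xy(detections_by_frame[t])
        res = assign(positions[:, t - 1], det_xy, max_gate_px=max_gate_px, method=method)
        for i in range(n_fish):
            j = res.mapping[i] if res.mapping else None
            if j is None:
                positions[i, t] = positions[i, t - 1]
            else:
                positions[i, t] = det_xy[j]
                observed[i, t] = True
                step = float(np.linalg.norm(positions[i, t] - positions[i, t - 1]))
                if step > 0.8 * max_gate_px:
                    n_suspects += 1
                    logger.warning(
                        "swap suspect: fish %d frame %d matched at %.1f px "
                        "(gate %.1f)", i, t, step, max_gate_px
                    )
    logger.info(
        "built %d tracks over %d frames (%d swap suspects)", n_fish, n_frames, n_suspects
    )
    return [
        Track(fish_id=i, positions=positions[i], observed=observed[i])
        for i in range(n_fish)
    ]


def count_identity_swaps(tracks: Sequence[Track], truth_positions: np.ndarray) -> int:
    """Count identity-swap events of tracks against ground truth.

    For each frame, each track is assigned its nearest ground-truth
    fish (optimal assignment); a swap event is any frame where a
    track's assigned identity differs from the previous frame's.
    ``truth_positions`` has shape (n_fish, n_frames, 2).
    """
    truth = np.asarray(truth_positions, dtype=np.float64)
    n_frames = truth.shape[1]
    prev_ids = None
    swaps = 0
    for t in range(n_frames):
        track_xy = np.array([tr.positions[t] for tr in tracks])
        cost = cdist(track_xy, truth[:, t])
        rows, cols = linear_sum_assignment(cost)
        ids = tuple(int(c) for _, c in sorted(zip(rows, cols)))
        if prev_ids is not None and ids != prev_ids:
            swaps += 1
        prev_ids = ids
    return swaps
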