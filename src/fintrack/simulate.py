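"""Synthetic tank videos and embryo cohorts with known ground truth.

Every downstream stage of the pipeline (detection, tracking, velocity,
occupancy, statistics) is testable without any recording because this
module produces the two raw observational units with ground truth
attached:

* ``simulate_tank`` renders a grayscale clip of one or more dark
  fish-like ellipses swimming over a static noisy background. Fish move
  by a first-order autoregressive (correlated) random walk — smooth,
  fish-like paths that give a nearest-distance tracker realistic
  ambiguity — with specular reflection at the walls and an optional
  constant-magnitude drift toward the tank center, emulating the
  center-dwelling preference observed in fish under static magnetic
  field exposure.
* ``simulate_embryo_cohort`` produces per-embryo daily stage series on
  the medaka staging ladder (stage 14, pre-mid-gastrula, through stage
  40, first fry / hatching, over ~15 days), with configurable
  abnormality and hatch-failure probabilities.

Both generators are fully determined by their config (including the
seed). Trajectories are drawn before any rendering noise, so ground
truth depends only on the seed and the motion parameters, never on the
rendering parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .detect import FrameStack
from .embryo import ABNORMALITY_FEATURES, EmbryoRecord

#: medaka staging ladder used for daily records
STAGE_LADDER = (14, 18, 22, 23, 28, 29, 30, 33, 35, 37, 39, 40)

#: default day -> expected stage schedule (standard medaka development
#: at laboratory temperature: stage 14 on day 0 through stage 40 on day 15)
DEFAULT_STAGE_SCHEDULE: dict[int, int] = {
    0: 14, 1: 18, 2: 22, 3: 23, 5: 28, 6: 29, 7: 30,
    8: 33, 9: 35, 10: 37, 13: 39, 15: 40,
}


@dataclass(frozen=True)
class TankSimConfig:
    """Parameters of the synthetic tank clip.

    Geometry defaults match the analyzed recordings of the assay this
    package targets: 380x380-pixel frames, 300-frame clips. The frame
    period defaults to 1 s so that a 300-frame clip spans the 5-minute
    clip length used for velocity normalization.
    """

    width_px: int = 380
    height_px: int = 380
    n_frames: int = 300
    frame_period_s: float = 1.0
    n_fish: int = 1
    fish_axes_px: tuple[float, float] = (7.0, 4.0)  # (x, y) ellipse semi-axes
    fish_intensity: int = 40
    background_intensity: int = 200
    noise_sigma: float = 2.0
    speed_scale_px: float = 1.5  # per-frame random velocity perturbation scale
    velocity_persistence: float = 0.8  # AR(1) coefficient, 0 = uncorrelated jumps
    center_bias: float = 0.0  # px/frame drift toward tank center, 0 = none
    seed: int = 0

    def validate(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) < 1:
            raise ValueError("width_px, height_px and n_frames must be positive")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        if self.n_fish < 0:
            raise ValueError("n_fish must be non-negative")
        ax, ay = self.fish_axes_px
        if ax <= 0 or ay <= 0:
            raise ValueError("fish semi-axes must be positive")
        if ax >= self.width_px / 2 or ay >= self.height_px / 2:
            raise ValueError("fish must fit inside the frame (semi-axes < half-dimension)")
        for name in ("fish_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in 0-255")
        if self.n_fish > 0 and self.fish_intensity == self.background_intensity:
            raise ValueError("fish_intensity must differ from background_intensity")
        if self.noise_sigma < 0 or self.speed_scale_px < 0 or self.center_bias < 0:
            raise ValueError("noise_sigma, speed_scale_px and center_bias must be >= 0")
        if not 0.0 <= self.velocity_persistence <= 1.0:
            raise ValueError("velocity_persistence must be in [0, 1]")


@dataclass
class GroundTruth:
    """True fish center positions, one per frame per fish.

    positions has shape (n_fish, n_frames, 2) in (x, y) pixel
    coordinates.
    """

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.size and self.positions.ndim != 3:
            raise ValueError("positions must be (n_fish, n_frames, 2)")
        self.positions = self.positions.reshape(self.positions.shape or (0, 0, 2))

    @property
    def n_fish(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for fish in range(self.n_fish):
            for frame in range(self.n_frames):
                x, y = self.positions[fish, frame]
                rows.append({"frame": frame, "fish_id": fish, "x": x, "y": y})
        return pd.DataFrame(rows, columns=["frame", "fish_id", "x", "y"])


def _reflect(pos: np.ndarray, vel: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Fold positions into [lo, hi] by specular reflection; flip velocity
    on each fold. Handles arbitrary overshoot via the triangle-wave map."""
    span = hi - lo
    q = np.mod(pos - lo, 2.0 * span)
    over = q > span
    pos_new = np.where(over, 2.0 * span - q, q) + lo
    vel_new = np.where(over, -vel, vel)
    # an even number of full bounces restores the velocity sign; the
    # triangle-wave fold above already accounts for that via the modulo
    return pos_new, vel_new


def simulate_trajectories(config: TankSimConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw the correlated-random-walk ground truth (no rendering).

    Per frame, for each fish:
    ``v <- persistence * v + eta + bias``, where eta is isotropic
    Gaussian noise of scale ``speed_scale_px`` and bias is a vector of
    magnitude ``center_bias`` pointing at the frame center; then
    ``p <- p + v`` with specular reflection keeping the whole fish body
    inside the frame.
    """
    n = config.n_fish
    if n == 0:
        return GroundTruth(np.zeros((0, config.n_frames, 2)))
    ax, ay = config.fish_axes_px
    lo = np.array([ax, ay])
    hi = np.array([config.width_px - 1 - ax, config.height_px - 1 - ay])
    center = np.array([(config.width_px - 1) / 2.0, (config.height_px - 1) / 2.0])

    pos = rng.uniform(lo, hi, size=(n, 2))
    vel = np.zeros((n, 2))
    out = np.empty((n, config.n_frames, 2))
    for t in range(config.n_frames):
        out[:, t] = pos
        eta = rng.normal(0.0, 1.0, size=(n, 2)) * config.speed_scale_px
        to_center = center - pos
        norm = np.linalg.norm(to_center, axis=1, keepdims=True)
        drift = config.center_bias * np.where(norm > 1e-9, to_center / norm, 0.0)
        vel = config.velocity_persistence * vel + eta + drift
        pos, vel = _reflect(pos + vel, vel, lo, hi)
    return GroundTruth(out)


def constant_speed_trajectory(
    config: TankSimConfig,
    speed_px_per_frame: float,
    angle_rad: float = 0.53,
    start: tuple[float, float] | None = None,
) -> GroundTruth:
    """Single-fish trajectory moving at exactly ``speed_px_per_frame``
    along ``angle_rad``, with specular wall reflection (which preserves
    speed). Useful for calibrating the velocity estimator against a
    known true speed.
    """
    config.validate()
    ax, ay = config.fish_axes_px
    lo = np.array([ax, ay])
    hi = np.array([config.width_px - 1 - ax, config.height_px - 1 - ay])
    pos = np.array(start, dtype=float) if start is not None else (lo + hi) / 3.0
    if np.any(pos < lo) or np.any(pos > hi):
        raise ValueError("start position must keep the fish inside the frame")
    vel = speed_px_per_frame * np.array([np.cos(angle_rad), np.sin(angle_rad)])
    out = np.empty((1, config.n_frames, 2))
    for t in range(config.n_frames):
        out[0, t] = pos
        p, v = _reflect((pos + vel)[None, :], vel[None, :], lo, hi)
        pos, vel = p[0], v[0]
    return GroundTruth(out)


def render_frames(
    truth: GroundTruth, config: TankSimConfig, rng: np.random.Generator
) -> FrameStack:
    """Render frames: flat background + Gaussian noise, fish as hard
    (non-anti-aliased) filled ellipses at their true positions.

    The hard ellipse mask makes blob areas exactly countable, so
    detector tests can use direct pixel-count oracles.
    """
    h, w = config.height_px, config.width_px
    ax, ay = config.fish_axes_px
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    cols = np.arange(w)
    rows = np.arange(h)
    for t in range(config.n_frames):
        img = np.full((h, w), float(config.background_intensity))
        if config.noise_sigma > 0:
            img += rng.normal(0.0, config.noise_sigma, size=(h, w))
        for fish in range(truth.n_fish):
            cx, cy = truth.positions[fish, t]
            c0 = max(int(np.floor(cx - ax)) - 1, 0)
            c1 = min(int(np.ceil(cx + ax)) + 2, w)
            r0 = max(int(np.floor(cy - ay)) - 1, 0)
            r1 = min(int(np.ceil(cy + ay)) + 2, h)
            xx = (cols[c0:c1] - cx) / ax
            yy = (rows[r0:r1] - cy) / ay
            mask = xx[None, :] ** 2 + yy[:, None] ** 2 <= 1.0
            sub = img[r0:r1, c0:c1]
            sub[mask] = float(config.fish_intensity)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameStack(frames=frames, frame_period_s=config.frame_period_s)


def simulate_tank(config: TankSimConfig) -> tuple[FrameStack, GroundTruth]:
    """Generate a synthetic tank clip and its ground-truth trajectories.

    All motion randomness is consumed before any rendering noise, so
    re-running only the motion model with the same seed reproduces the
    ground truth exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = simulate_trajectories(config, rng)
    stack = render_frames(truth, config, rng)
    return stack, truth


# ---------------------------------------------------------------------------
# embryo cohorts


@dataclass(frozen=True)
class EmbryoSimConfig:
    """Parameters of a synthetic embryo cohort.

    Defaults mirror the exposed arm of a typical dish experiment: five
    dishes of 15 embryos, daily staging over 15 days following the
    standard medaka schedule, a ~2.7% abnormality probability, a small
    hatch-failure probability, and hatch days centered on day 15.
    """

    n_dishes: int = 5
    embryos_per_dish: int = 15
    stage_schedule: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_SCHEDULE)
    )
    stage_noise_sd: float = 1.0
    p_abnormal: float = 2.0 / 75.0
    p_hatch_fail: float = 0.05
    hatch_day_mean: float = 15.0
    hatch_day_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_dishes < 1 or self.embryos_per_dish < 1:
            raise ValueError("n_dishes and embryos_per_dish must be positive")
        if not self.stage_schedule:
            raise ValueError("stage_schedule must be non-empty")
        days = sorted(self.stage_schedule)
        stages = [self.stage_schedule[d] for d in days]
        if any(s2 < s1 for s1, s2 in zip(stages, stages[1:])):
            raise ValueError("stage_schedule must be monotone non-decreasing in day")
        for name in ("p_abnormal", "p_hatch_fail"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.stage_noise_sd < 0:
            raise ValueError("stage_noise_sd must be >= 0")
        if self.hatch_day_mean <= 0 or self.hatch_day_sd <= 0:
            raise ValueError("hatch_day_mean and hatch_day_sd must be positive")


def expand_stage_schedule(schedule: Mapping[int, int]) -> np.ndarray:
    """Daily expected stages for days 0..max(schedule): days between
    listed entries take the nearest lower listed stage."""
    days = sorted(schedule)
    out = np.empty(days[-1] + 1, dtype=np.int64)
    current = schedule[days[0]]
    for d in range(days[-1] + 1):
        if d in schedule:
            current = schedule[d]
        out[d] = current
    return out


def simulate_embryo_cohort(config: EmbryoSimConfig) -> list[EmbryoRecord]:
    """Generate a seeded cohort of embryo records.

    Each embryo's daily stage is the schedule value plus rounded
    Gaussian noise (sd ``stage_noise_sd``), clamped monotone
    non-decreasing by a running maximum and bounded by the terminal
    stage 40 (39 for embryos that never hatch, which by definition do
    not reach the first-fry stage). Abnormality flags are Bernoulli
    with ``p_abnormal``; the hatch day is Gaussian
    (``hatch_day_mean``, ``hatch_day_sd``) or absent with probability
    ``p_hatch_fail``; it is never earlier than the day the stage series
    reaches the first-fry stage (40).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    daily = expand_stage_schedule(config.stage_schedule)
    n_days = daily.size
    n_total = config.n_dishes * config.embryos_per_dish

    noise = np.rint(rng.normal(0.0, 1.0, size=(n_total, n_days)) * config.stage_noise_sd)
    stages = daily[None, :] + noise.astype(np.int64)
    stages = np.maximum.accumulate(stages, axis=1)
    stages = np.clip(stages, STAGE_LADDER[0], STAGE_LADDER[-1])

    abnormal = rng.random(n_total) < config.p_abnormal
    features = rng.integers(0, len(ABNORMALITY_FEATURES), size=n_total)
    hatch_fail = rng.random(n_total) < config.p_hatch_fail
    hatch_draw = np.maximum(
        rng.normal(config.hatch_day_mean, config.hatch_day_sd, size=n_total), 1.0
    )

    # hatching corresponds to reaching the first-fry stage (40): the hatch
    # day cannot precede the day the stage series reaches 40, and the
    # recorded stage is 40 from the hatch day onward; embryos that never
    # hatch never reach stage 40
    final = STAGE_LADDER[-1]
    hatch_days = hatch_draw.copy()
    for i in range(n_total):
        if hatch_fail[i]:
            stages[i] = np.minimum(stages[i], final - 1)
            continue
        at_final = np.flatnonzero(stages[i] == final)
        if at_final.size:
            hatch_days[i] = max(hatch_draw[i], float(at_final[0]))
        else:
            start = int(np.ceil(hatch_days[i]))
            if start < n_days:
                stages[i, start:] = final

    records = []
    for i in range(n_total):
        dish = i // config.embryos_per_dish
        records.append(
            EmbryoRecord(
                dish_id=dish,
                embryo_id=i % config.embryos_per_dish,
                daily_stages={d: int(stages[i, d]) for d in range(n_days)},
                abnormal=bool(abnormal[i]),
                abnormal_feature=ABNORMALITY_FEATURES[features[i]] if abnormal[i] else None,
                hatch_day=None if hatch_fail[i] else float(np.round(hatch_days[i], 1)),
            )
        )
    return records
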