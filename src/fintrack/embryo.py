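"""Embryo-cohort endpoints: hatchability, days to hatch, abnormality rate,
and developmental stage-curve comparison.

Medaka embryos are observed daily and assigned a stage on the standard
staging ladder (14 = pre-mid-gastrula through 40 = first fry, the
hatching stage). A dish's hatchability is the percentage of its embryos
that hatch before the abandonment cutoff; the abnormality rate is the
percentage of embryos flagged with any morphological abnormality (body
length, head circumference, eye symmetry, spine shape, tail shape,
heart shape). Two groups' developmental trajectories are compared by a
paired t-test on their day-matched mean stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import PairedTTestResult, paired_t_test

#: observable morphological features used for abnormality annotation
ABNORMALITY_FEATURES = (
    "body length",
    "head circumference",
    "eye symmetry",
    "spine shape",
    "tail shape",
    "heart shape",
)

#: default abandonment cutoff: embryos unhatched after this many days
#: count as unhatched
DEFAULT_ABANDON_AFTER_DAYS = 20


@dataclass
class EmbryoRecord:
    """Daily observations of one embryo.

    daily_stages maps observation day (0-based) to the stage recorded
    that day; stages are monotone non-decreasing. hatch_day is None for
    embryos that never hatched.
    """

    dish_id: int
    embryo_id: int
    daily_stages: dict[int, int]
    abnormal: bool = False
    abnormal_feature: str | None = None
    hatch_day: float | None = None

    def __post_init__(self) -> None:
        days = sorted(self.daily_stages)
        stages = [self.daily_stages[d] for d in days]
        if any(s2 < s1 for s1, s2 in zip(stages, stages[1:])):
            raise ValueError(
                f"dish {self.dish_id} embryo {self.embryo_id}: stages must be "
                "monotone non-decreasing in day"
            )

    def hatched_by(self, day: float) -> bool:
        return self.hatch_day is not None and self.hatch_day <= day


@dataclass(frozen=True)
class DishSummary:
    dish_id: int
    n_total: int
    n_hatched: int
    hatchability_pct: float
    mean_days_to_hatch: float  # NaN when no embryo hatched


def summarize_dish(
    records: Sequence[EmbryoRecord],
    abandon_after_days: float = DEFAULT_ABANDON_AFTER_DAYS,
) -> DishSummary:
    """Summarize one dish: hatch count, hatchability %, mean days to hatch.

    Embryos not hatched by ``abandon_after_days`` count as unhatched.
    Hatchability is rounded to one decimal; mean days to hatch averages
    over hatched embryos only.
    """
    records = list(records)
    if not records:
        raise ValueError("dish has no records")
    dish_ids = {r.dish_id for r in records}
    if len(dish_ids) > 1:
        raise ValueError(f"records span several dishes: {sorted(dish_ids)}")
    hatch_days = [
        r.hatch_day for r in records if r.hatched_by(abandon_after_days)
    ]
    n_total = len(records)
    n_hatched = len(hatch_days)
    return DishSummary(
        dish_id=records[0].dish_id,
        n_total=n_total,
        n_hatched=n_hatched,
        hatchability_pct=round(100.0 * n_hatched / n_total, 1),
        mean_days_to_hatch=float(np.mean(hatch_days)) if hatch_days else math.nan,
    )


def summarize_cohort(
    records: Sequence[EmbryoRecord],
    abandon_after_days: float = DEFAULT_ABANDON_AFTER_DAYS,
) -> pd.DataFrame:
    """Per-dish summary table (one row per dish, hatch endpoints as columns)."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    rows = []
    for dish_id in sorted({r.dish_id for r in records}):
        s = summarize_dish(
            [r for r in records if r.dish_id == dish_id], abandon_after_days
        )
        rows.append(
            {
                "dish": s.dish_id,
                "total": s.n_total,
                "hatched": s.n_hatched,
                "hatchability_pct": s.hatchability_pct,
                "mean_days_to_hatch": round(s.mean_days_to_hatch, 1)
                if not math.isnan(s.mean_days_to_hatch)
                else math.nan,
            }
        )
    return pd.DataFrame(rows)


def abnormality_rate(records: Sequence[EmbryoRecord]) -> float:
    """Percentage of embryos flagged abnormal, rounded to one decimal."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    n_abnormal = sum(1 for r in records if r.abnormal)
    return round(100.0 * n_abnormal / len(records), 1)


def mean_stage_curve(records: Sequence[EmbryoRecord]) -> pd.Series:
    """Day-indexed mean developmental stage over a cohort."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    frames = pd.DataFrame([r.daily_stages for r in records])
    curve = frames.mean(axis=0)
    curve.index.name = "day"
    return curve.sort_index()


def compare_stage_curves(
    group_a: pd.Series | Mapping[int, float] | Sequence[float],
    group_b: pd.Series | Mapping[int, float] | Sequence[float],
) -> PairedTTestResult:
    """Paired t-test of two day-matched mean-stage trajectories.

    Both curves must be defined on the same day grid; pairing is by day.
    """
    a = pd.Series(dict(group_a)) if isinstance(group_a, Mapping) else pd.Series(group_a)
    b = pd.Series(dict(group_b)) if isinstance(group_b, Mapping) else pd.Series(group_b)
    if not a.index.equals(b.index):
        raise ValueError("stage curves are on different day grids")
    return paired_t_test(a.to_numpy(), b.to_numpy())
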