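"""Synthetic benchmark plan and DTW-based plan similarity.

The reference 8-week plan emulates a conventional coached periodized
schedule: each week alternates harder and easier days around one full
rest day, volume progresses gently week over week, and every fourth
week is a reduced recovery week.  The generator guarantees the result
satisfies all physiological constraints, which is what makes it a
meaningful comparison target for optimized plans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constraints import ConstraintConfig, violations
from .physiology import (
    AthleteProfile,
    TrainingPlan,
    trimp_series,
    zone_table,
)

__all__ = [
    "BenchmarkSpec",
    "SimilarityResult",
    "synth_standard_plan",
    "dtw_distance",
    "dtw_similarity",
    "extreme_load_normalizer",
]

#: Weekly template: heart-rate zone per day (None = full rest day).
DEFAULT_DAY_ZONES: tuple = (3, 1, 2, None, 3, 1, 0)
#: Weekly template: session duration per day, minutes.
DEFAULT_DAY_DURATIONS: tuple = (32.0, 32.0, 30.0, 30.0, 30.0, 30.0, 30.0)


class GenerationError(RuntimeError):
    """The requested benchmark spec cannot produce a feasible plan."""


@dataclass(frozen=True)
class BenchmarkSpec:
    weeks: int = 8
    sessions_per_week: int = 7
    hard_day_pattern: tuple = DEFAULT_DAY_ZONES
    day_durations: tuple = DEFAULT_DAY_DURATIONS
    recovery_week_period: int = 4
    recovery_factor: float = 0.6
    progression: float = 1.03      # weekly duration multiplier
    hr_jitter_bpm: float = 1.0
    duration_jitter_min: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hard_day_pattern) != self.sessions_per_week:
            raise ValueError("hard_day_pattern length must equal sessions_per_week")
        if len(self.day_durations) != self.sessions_per_week:
            raise ValueError("day_durations length must equal sessions_per_week")


@dataclass(frozen=True)
class SimilarityResult:
    dtw_distance: float
    similarity: float


def synth_standard_plan(spec: BenchmarkSpec = BenchmarkSpec(),
                        athlete: AthleteProfile | None = None,
                        constraint_cfg: ConstraintConfig = ConstraintConfig(),
                        duration_bounds: tuple[float, float] = (30.0, 300.0)) -> TrainingPlan:
    """Deterministic, constraint-feasible standard plan for ``athlete``."""
    if athlete is None:
        from .physiology import simulated_athlete
        athlete = simulated_athlete()
    rng = np.random.default_rng(spec.rng_seed)
    zones = zone_table(athlete)
    lo_d, hi_d = duration_bounds

    hrs: list[float] = []
    durs: list[float] = []
    for w in range(spec.weeks):
        mult = spec.progression ** w
        if (w + 1) % spec.recovery_week_period == 0:
            mult *= spec.recovery_factor
        for zone, base_dur in zip(spec.hard_day_pattern, spec.day_durations):
            if zone is None:
                hrs.append(athlete.resting_hr)
                durs.append(lo_d)
                continue
            row = zones[zone]
            hr = 0.5 * (row["hr_lo_bpm"] + row["hr_hi_bpm"])
            hr += rng.uniform(-spec.hr_jitter_bpm, spec.hr_jitter_bpm)
            dur = base_dur * mult + rng.uniform(-spec.duration_jitter_min,
                                                spec.duration_jitter_min)
            hrs.append(float(np.clip(hr, athlete.resting_hr, athlete.max_hr)))
            durs.append(float(np.clip(dur, lo_d, hi_d)))

    plan = TrainingPlan.from_arrays(hrs, durs)
    report = violations(plan, athlete, constraint_cfg)
    if not report.feasible:
        broken = [name for name, g in [("monotony", report.g_monotony),
                                       ("ctl_ramp_rate", report.g_ramp),
                                       ("daily_trimp", report.g_daily)] if g > 0]
        raise GenerationError(
            f"spec produces an infeasible plan (violated: {', '.join(broken)}; "
            f"phi={report.total_violation:.4g})"
        )
    return plan


def dtw_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Classic dynamic-time-warping cost with |x - y| local distance.

    Unit step pattern {(1,0), (0,1), (1,1)}, no window constraint.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(acc[i - 1, j],
                                                 acc[i, j - 1],
                                                 acc[i - 1, j - 1])
    return float(acc[n, m])


def extreme_load_normalizer(athlete: AthleteProfile, n: int,
                            duration_bounds: tuple[float, float] = (30.0, 300.0)) -> float:
    """DTW distance between the two most extreme plans of length ``n``.

    The "furthest apart" plans are every-day-minimum-load (resting HR,
    hence zero TRIMP) versus every-day-maximum-load (max HR for the
    longest allowed duration).
    """
    hi_load = duration_bounds[1] * 1.0 * float(np.exp(athlete.sex_factor_y))
    return dtw_distance(np.zeros(n), np.full(n, hi_load))


def dtw_similarity(a: Sequence[float], b: Sequence[float],
                   normalizer: float | None = None,
                   athlete: AthleteProfile | None = None,
                   duration_bounds: tuple[float, float] = (30.0, 300.0),
                   mode: str = "extremes") -> SimilarityResult:
    """Bounded similarity of two daily-load series: 1 identical, 0 extremes.

    ``similarity = 1 - dtw / normalizer`` clipped to [0, 1].  The
    default normalizer (``mode="extremes"``) is the DTW distance
    between the all-minimum and all-maximum load plans of the same
    length; ``mode="path"`` normalizes by per-step cost over the
    longer series length times the larger value range instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = dtw_distance(a, b)
    if normalizer is None:
        if mode == "extremes":
            if athlete is None:
                raise ValueError("need athlete (or explicit normalizer) for mode='extremes'")
            normalizer = extreme_load_normalizer(athlete, max(a.size, b.size),
                                                 duration_bounds)
        elif mode == "path":
            rng_ = max(np.ptp(np.concatenate([a, b])), 1e-12)
            normalizer = float(max(a.size, b.size)) * rng_
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if normalizer <= 0:
        raise ValueError(f"normalizer must be > 0, got {normalizer}")
    return SimilarityResult(dtw_distance=d,
                            similarity=float(np.clip(1.0 - d / normalizer, 0.0, 1.0)))
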