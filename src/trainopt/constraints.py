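"""Physiological constraint metrics and the epsilon-comparison.

Three inequality constraints keep a generated plan clear of
overtraining risk:

1. weekly training monotony (mean daily load / sd of daily load,
   per 7-day block) must not exceed 1.5;
2. the weekly ramp rate of chronic training load (42-day EWMA of daily
   load) must stay at or under 5 TRIMP/day per week;
3. no single day may exceed 450 TRIMP.

Violation magnitudes are normalized by their thresholds so the three
constraints contribute on comparable scales, then aggregated as
``phi = g1**p + g2**p + g3**p`` (default p = 2).  Candidate solutions
are ordered by ``epsilon_compare``: violation first (relaxed by the
epsilon level), objective second.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .physiology import AthleteProfile, TrainingPlan, trimp_series

__all__ = [
    "ConstraintConfig",
    "ConstraintReport",
    "weekly_monotony",
    "ctl_series",
    "weekly_ramp_rates",
    "violations",
    "epsilon_compare",
    "is_better",
]


@dataclass(frozen=True)
class ConstraintConfig:
    monotony_max: float = 1.5
    ramp_rate_max: float = 5.0
    daily_trimp_max: float = 450.0
    ctl_time_constant: float = 42.0
    ctl_start: float = 0.0
    violation_exponent: int = 2
    week_length: int = 7
    # finite stand-in for an infinite monotony ratio (zero-variance week
    # with nonzero load), keeping phi arithmetic well-defined
    infinite_monotony_penalty: float = 10.0
    # aggregate per-week excesses by summing (default) or take the worst week
    aggregate: str = "sum"

    def __post_init__(self) -> None:
        if min(self.monotony_max, self.ramp_rate_max, self.daily_trimp_max,
               self.ctl_time_constant) <= 0:
            raise ValueError("constraint thresholds must be > 0")
        if self.violation_exponent < 1:
            raise ValueError("violation_exponent must be >= 1")
        if self.aggregate not in ("sum", "max"):
            raise ValueError("aggregate must be 'sum' or 'max'")


@dataclass(frozen=True)
class ConstraintReport:
    """Raw metrics, per-constraint violations and the aggregate phi."""

    weekly_monotony: tuple[float, ...]
    ctl: tuple[float, ...]
    weekly_ramp_rates: tuple[float, ...]
    daily_trimp: tuple[float, ...]
    g_monotony: float
    g_ramp: float
    g_daily: float
    total_violation: float

    @property
    def feasible(self) -> bool:
        return self.total_violation == 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feasible"] = self.feasible
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def weekly_monotony(loads: Sequence[float], cfg: ConstraintConfig = ConstraintConfig()) -> np.ndarray:
    """Foster monotony per 7-day block: mean daily load / sample sd.

    All-zero weeks score 0 (a rest week is not monotonous training);
    constant nonzero weeks have zero variance and score ``inf``.
    A trailing partial week is ignored.
    """
    loads = np.asarray(loads, dtype=float)
    if loads.size == 0:
        raise ValueError("empty load series")
    wl = cfg.week_length
    n_weeks = loads.size // wl
    if n_weeks == 0:
        raise ValueError(f"need at least one full {wl}-day week, got {loads.size} days")
    weeks = loads[: n_weeks * wl].reshape(n_weeks, wl)
    mean = weeks.mean(axis=1)
    sd = weeks.std(axis=1, ddof=1)
    out = np.empty(n_weeks)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    out[mean == 0] = 0.0
    return out


def ctl_series(loads: Sequence[float], cfg: ConstraintConfig = ConstraintConfig()) -> np.ndarray:
    """Chronic training load: EWMA with time constant ``ctl_time_constant``.

    ``CTL_t = CTL_{t-1} + (w_t - CTL_{t-1}) / tau`` starting from
    ``ctl_start`` (default 0, a novice athlete).
    """
    loads = np.asarray(loads, dtype=float)
    if np.any(loads < 0):
        raise ValueError(f"negative load at day {int(np.argmax(loads < 0)) + 1}")
    tau = cfg.ctl_time_constant
    out = np.empty(loads.size)
    ctl = cfg.ctl_start
    for t, w in enumerate(loads):
        ctl += (w - ctl) / tau
        out[t] = ctl
    return out


def weekly_ramp_rates(ctl: Sequence[float], cfg: ConstraintConfig = ConstraintConfig()) -> np.ndarray:
    """Week-over-week CTL change: CTL at day 7k minus CTL at day 7(k-1)."""
    ctl = np.asarray(ctl, dtype=float)
    wl = cfg.week_length
    ends = ctl[wl - 1 :: wl]
    return np.diff(np.concatenate(([cfg.ctl_start], ends)))


def _aggregate(excess: np.ndarray, cfg: ConstraintConfig) -> float:
    if excess.size == 0:
        return 0.0
    return float(excess.max() if cfg.aggregate == "max" else excess.sum())


def violations_from_loads(loads: Sequence[float],
                          cfg: ConstraintConfig = ConstraintConfig()) -> ConstraintReport:
    """ConstraintReport for a daily TRIMP series."""
    loads = np.asarray(loads, dtype=float)
    mono = weekly_monotony(loads, cfg)
    ctl = ctl_series(loads, cfg)
    ramps = weekly_ramp_rates(ctl, cfg)

    mono_excess = np.maximum(0.0, mono - cfg.monotony_max) / cfg.monotony_max
    mono_excess = np.where(np.isinf(mono_excess), cfg.infinite_monotony_penalty, mono_excess)
    ramp_excess = np.maximum(0.0, ramps - cfg.ramp_rate_max) / cfg.ramp_rate_max
    daily_excess = np.maximum(0.0, loads - cfg.daily_trimp_max) / cfg.daily_trimp_max

    g1 = _aggregate(mono_excess, cfg)
    g2 = _aggregate(ramp_excess, cfg)
    g3 = _aggregate(daily_excess, cfg)
    p = cfg.violation_exponent
    return ConstraintReport(
        weekly_monotony=tuple(mono),
        ctl=tuple(ctl),
        weekly_ramp_rates=tuple(ramps),
        daily_trimp=tuple(loads),
        g_monotony=g1,
        g_ramp=g2,
        g_daily=g3,
        total_violation=g1 ** p + g2 ** p + g3 ** p,
    )


def violations(plan: TrainingPlan, athlete: AthleteProfile,
               cfg: ConstraintConfig = ConstraintConfig()) -> ConstraintReport:
    """ConstraintReport for a training plan."""
    return violations_from_loads(trimp_series(plan, athlete), cfg)


def is_better(a: tuple[float, float], b: tuple[float, float],
              epsilon: float = 0.0) -> bool:
    """True if candidate ``a`` strictly beats ``b`` under epsilon-comparison.

    Candidates are ``(objective, phi)`` with larger objective better and
    phi >= 0.  Violations at or under ``epsilon`` are treated as zero;
    otherwise the smaller violation wins, and the objective decides ties.
    """
    obj_a, phi_a = a
    obj_b, phi_b = b
    ea = 0.0 if phi_a <= epsilon else phi_a
    eb = 0.0 if phi_b <= epsilon else phi_b
    if ea != eb:
        return ea < eb
    return obj_a > obj_b


def epsilon_compare(a: tuple[float, float], b: tuple[float, float],
                    epsilon: float = 0.0) -> tuple[float, float]:
    """Return the better of two ``(objective, phi)`` candidates (ties -> a)."""
    return b if is_better(b, a, epsilon) else a
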