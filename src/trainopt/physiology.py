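"""Heart-rate physiology: TRIMP session loads and the Banister
impulse-response performance model.

The performance model treats each training day as an impulse of load
(TRIMP units) that feeds two antagonistic first-order responses:
a slowly decaying fitness gain and a quickly decaying but larger
fatigue gain.  Performance on day ``t`` is::

    p_t = p0 + k1 * sum_{i=0}^{t-1} w_i * exp(-(t - i) / r1)
             - k2 * sum_{i=0}^{t-1} w_i * exp(-(t - i) / r2)

Sessions 1..M are mapped to days i = 0..M-1, so the session on day i
affects performance from day i + 1 onward.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AthleteProfile",
    "TrainingSession",
    "TrainingPlan",
    "BanisterParameters",
    "PerformanceSeries",
    "SEX_FACTORS",
    "normalized_hr",
    "session_trimp",
    "trimp_series",
    "performance",
    "performance_series",
    "plan_fitness",
    "hr_zone_of",
    "zone_table",
    "HR_ZONE_LOWER_PCT",
    "HR_ZONE_LOWER_PCT_PRINTED",
    "DURATION_ZONES_MIN",
]

#: TRIMP exponent constant by sex.
SEX_FACTORS = {"male": 1.92, "female": 1.67}


class DomainError(ValueError):
    """A physiological quantity is outside its valid range."""


@dataclass(frozen=True)
class AthleteProfile:
    """Physiological constants of one athlete."""

    resting_hr: float
    max_hr: float
    fthr: float
    sex_factor_y: float = SEX_FACTORS["male"]
    baseline_performance_p0: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.resting_hr < self.fthr < self.max_hr):
            raise DomainError(
                f"require 0 < resting_hr < fthr < max_hr, got "
                f"{self.resting_hr}, {self.fthr}, {self.max_hr}"
            )
        if self.sex_factor_y <= 0:
            raise DomainError(f"sex_factor_y must be > 0, got {self.sex_factor_y}")

    @property
    def hr_range(self) -> float:
        return self.max_hr - self.resting_hr

    @classmethod
    def from_dict(cls, d: dict) -> "AthleteProfile":
        y = d.get("sex_factor_y")
        if y is None:
            sex = d.get("sex", "male")
            try:
                y = SEX_FACTORS[sex]
            except KeyError:
                raise DomainError(f"unknown sex {sex!r}; give sex_factor_y explicitly")
        return cls(
            resting_hr=float(d["resting_hr"]),
            max_hr=float(d["max_hr"]),
            fthr=float(d["fthr"]),
            sex_factor_y=float(y),
            baseline_performance_p0=float(d.get("p0", d.get("baseline_performance_p0", 0.0))),
        )

    @classmethod
    def from_json(cls, path) -> "AthleteProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "resting_hr": self.resting_hr,
            "max_hr": self.max_hr,
            "fthr": self.fthr,
            "sex_factor_y": self.sex_factor_y,
            "p0": self.baseline_performance_p0,
        }


#: The simulated 35-year-old male cyclist used throughout the tests.
def simulated_athlete(p0: float = 0.0) -> AthleteProfile:
    return AthleteProfile(resting_hr=51, max_hr=189, fthr=165,
                          sex_factor_y=SEX_FACTORS["male"],
                          baseline_performance_p0=p0)


@dataclass(frozen=True)
class TrainingSession:
    """One session: average heart rate (bpm) and duration (minutes)."""

    avg_hr: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise DomainError(f"duration must be >= 0, got {self.duration_min}")


@dataclass(frozen=True)
class TrainingPlan:
    """Ordered sequence of training sessions (one per day)."""

    sessions: tuple[TrainingSession, ...]

    def __init__(self, sessions: Sequence[TrainingSession]):
        object.__setattr__(self, "sessions", tuple(sessions))

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def __getitem__(self, i):
        return self.sessions[i]

    @classmethod
    def from_arrays(cls, avg_hr: Sequence[float], duration_min: Sequence[float]) -> "TrainingPlan":
        if len(avg_hr) != len(duration_min):
            raise ValueError("avg_hr and duration_min must have equal length")
        return cls([TrainingSession(float(h), float(d))
                    for h, d in zip(avg_hr, duration_min)])

    @property
    def avg_hrs(self) -> np.ndarray:
        return np.array([s.avg_hr for s in self.sessions], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([s.duration_min for s in self.sessions], dtype=float)


@dataclass(frozen=True)
class BanisterParameters:
    """Fitness/fatigue impulse-response constants.

    Defaults follow the published model fit of Busso and colleagues
    (fitness gain 0.031, fatigue gain 0.087 per TRIMP; decay time
    constants 30.8 and 16.8 days).  Physiologically the fatigue
    amplitude and decay rate exceed the fitness ones; violating that
    ordering is legal but warned about.
    """

    k1: float = 0.031
    k2: float = 0.087
    r1: float = 30.8
    r2: float = 16.8

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.r1, self.r2) <= 0:
            raise DomainError("all Banister parameters must be > 0")
        if not (self.k2 > self.k1 and self.r1 > self.r2):
            warnings.warn(
                "expected k2 > k1 and r1 > r2 (fatigue larger amplitude, "
                f"faster decay); got k1={self.k1}, k2={self.k2}, "
                f"r1={self.r1}, r2={self.r2}",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {"k1": self.k1, "k2": self.k2, "r1": self.r1, "r2": self.r2}


@dataclass(frozen=True)
class PerformanceSeries:
    """Day-by-day decomposition of modelled performance.

    ``performance[t-1] == p0 + fitness[t-1] - fatigue[t-1]`` exactly.
    """

    days: np.ndarray          # 1..M
    performance: np.ndarray
    fitness: np.ndarray
    fatigue: np.ndarray
    loads: np.ndarray         # w_1..w_M, TRIMP
    p0: float = 0.0

    def __len__(self) -> int:
        return len(self.days)


def normalized_hr(avg_hr: float, athlete: AthleteProfile):
    """Fraction of heart-rate reserve: (hr - resting) / (max - resting)."""
    hr = np.asarray(avg_hr, dtype=float)
    if np.any(hr < athlete.resting_hr) or np.any(hr > athlete.max_hr):
        bad = hr[(hr < athlete.resting_hr) | (hr > athlete.max_hr)]
        raise DomainError(
            f"avg_hr {np.atleast_1d(bad)[0]} outside athlete range "
            f"[{athlete.resting_hr}, {athlete.max_hr}]"
        )
    out = (hr - athlete.resting_hr) / athlete.hr_range
    return float(out) if np.isscalar(avg_hr) or out.ndim == 0 else out


def session_trimp(session: TrainingSession, athlete: AthleteProfile) -> float:
    """TRIMP load of one session: d * normHR * exp(y * normHR)."""
    nh = normalized_hr(session.avg_hr, athlete)
    return session.duration_min * nh * float(np.exp(athlete.sex_factor_y * nh))


def trimp_series(plan: TrainingPlan, athlete: AthleteProfile) -> np.ndarray:
    """Per-session TRIMP loads w_1..w_M."""
    nh = normalized_hr(plan.avg_hrs, athlete)
    return plan.durations * nh * np.exp(athlete.sex_factor_y * nh)


def _convolve(loads: np.ndarray, r: float) -> np.ndarray:
    """For every t in 1..M: sum_{i=0}^{t-1} w_{i+1} * exp(-(t-i)/r).

    Computed by the prefix recursion
    ``s_t = (s_{t-1} + w_t) * exp(-1/r)`` which equals the double loop
    exactly (tested against the naive oracle).
    """
    decay = np.exp(-1.0 / r)
    out = np.empty(len(loads))
    acc = 0.0
    for t, w in enumerate(loads):
        acc = (acc + w) * decay
        out[t] = acc
    return out


def performance_series(plan: TrainingPlan, athlete: AthleteProfile,
                       params: BanisterParameters) -> PerformanceSeries:
    """Full performance/fitness/fatigue series over the plan's days."""
    loads = trimp_series(plan, athlete)
    fitness = params.k1 * _convolve(loads, params.r1)
    fatigue = params.k2 * _convolve(loads, params.r2)
    p0 = athlete.baseline_performance_p0
    return PerformanceSeries(
        days=np.arange(1, len(loads) + 1),
        performance=p0 + fitness - fatigue,
        fitness=fitness,
        fatigue=fatigue,
        loads=loads,
        p0=p0,
    )


def performance(plan: TrainingPlan, athlete: AthleteProfile,
                params: BanisterParameters, t: int) -> float:
    """Modelled performance on day ``t`` (1-based, 1 <= t <= M)."""
    if not 1 <= t <= len(plan):
        raise IndexError(f"day {t} out of range 1..{len(plan)}")
    return float(performance_series(plan, athlete, params).performance[t - 1])


def plan_fitness(plan: TrainingPlan, athlete: AthleteProfile,
                 params: BanisterParameters, objective: str = "final") -> float:
    """Scalar objective of a plan.

    ``objective="final"`` (default) is performance on the last day;
    ``"max"`` takes the best day instead.
    """
    series = performance_series(plan, athlete, params)
    if objective == "final":
        return float(series.performance[-1])
    if objective == "max":
        return float(series.performance.max())
    raise ValueError(f"unknown objective {objective!r}")


# Heart-rate zone lower boundaries as % of FTHR (zone 0..9); the upper
# boundary of zone 9 is the athlete's maximum heart rate.  Derived from
# the standard FTHR-anchored zone table of the 165-bpm-FTHR reference
# athlete (51, 82, 113, 125, 137, 147, 156, 166, 174, 182 bpm).
HR_ZONE_LOWER_PCT = np.array(
    [30.91, 49.70, 68.48, 75.76, 83.03, 89.09, 94.55, 100.61, 105.45, 110.30]
)

# As printed, zones 3 and 4 share the bpm interval 137-146 even though
# zone 3's percentages imply 125-136 bpm.  The percentage-consistent
# table above is the default; this variant keeps the printed bpm rows.
HR_ZONE_LOWER_PCT_PRINTED = np.array(
    [30.91, 49.70, 68.48, 83.03, 83.03, 89.09, 94.55, 100.61, 105.45, 110.30]
)

#: Duration zone upper bounds, minutes (zones 0..9, 30-minute steps).
DURATION_ZONES_MIN = np.array([30, 60, 90, 120, 150, 180, 210, 240, 270, 300])


def _zone_lower_bpm(athlete: AthleteProfile, table: np.ndarray) -> np.ndarray:
    """Integer bpm lower boundaries of each zone for this athlete.

    Boundaries are anchored as percentages of FTHR; rounding to whole
    bpm reproduces the reference athlete's published bpm columns.
    """
    return np.rint(table * athlete.fthr / 100.0)


def hr_zone_of(avg_hr: float, athlete: AthleteProfile,
               table: np.ndarray = HR_ZONE_LOWER_PCT) -> int:
    """Zone index 0..9 whose heart-rate interval contains ``avg_hr``."""
    if not athlete.resting_hr <= avg_hr <= athlete.max_hr:
        raise DomainError(
            f"avg_hr {avg_hr} outside athlete range "
            f"[{athlete.resting_hr}, {athlete.max_hr}]"
        )
    lowers = _zone_lower_bpm(athlete, table)
    idx = np.searchsorted(lowers, avg_hr, side="right") - 1
    return int(max(idx, 0))


def zone_table(athlete: AthleteProfile,
               table: np.ndarray = HR_ZONE_LOWER_PCT) -> list[dict]:
    """Per-zone bpm and %-of-FTHR boundaries for ``athlete``.

    Adjacent zones are separated by 1 bpm (integer-bpm convention);
    percentages are ``round(100 * bpm / fthr, 2)``.
    """
    lowers = _zone_lower_bpm(athlete, table)
    rows = []
    for z in range(len(lowers)):
        lo_bpm = lowers[z]
        hi_bpm = athlete.max_hr if z + 1 == len(lowers) else lowers[z + 1] - 1
        rows.append({
            "zone": z,
            "hr_lo_bpm": float(lo_bpm),
            "hr_hi_bpm": float(hi_bpm),
            "hr_lo_pct_fthr": round(100.0 * lo_bpm / athlete.fthr, 2),
            "hr_hi_pct_fthr": round(100.0 * hi_bpm / athlete.fthr, 2),
            "duration_hi_min": int(DURATION_ZONES_MIN[z]),
        })
    return rows
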