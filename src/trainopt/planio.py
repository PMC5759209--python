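"""Plan/trace file formats, YAML configuration and batch runs."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .constraints import ConstraintConfig, ConstraintReport
from .physiology import (
    AthleteProfile,
    BanisterParameters,
    PerformanceSeries,
    TrainingPlan,
)
from .pso import OptimizationResult, SwarmConfig, optimize

__all__ = [
    "PlanFormatError",
    "read_plan",
    "write_plan",
    "load_config",
    "RunRecord",
    "run_batch",
    "summarize_runs",
]

PLAN_COLUMNS = ["day", "avg_hr_bpm", "duration_min"]


class PlanFormatError(ValueError):
    pass


def read_plan(path) -> TrainingPlan:
    """Read a plan CSV (columns day, avg_hr_bpm, duration_min; days 1..M)."""
    df = pd.read_csv(path)
    missing = [c for c in PLAN_COLUMNS if c not in df.columns]
    if missing:
        raise PlanFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for row, (got, want) in enumerate(zip(df["day"], range(1, len(df) + 1)), start=1):
        if got != want:
            raise PlanFormatError(
                f"{path}: non-contiguous day numbering at row {row} "
                f"(expected day {want}, got {got})"
            )
    for row, d in enumerate(df["duration_min"], start=1):
        if d < 0:
            raise PlanFormatError(f"{path}: negative duration at row {row}")
    return TrainingPlan.from_arrays(df["avg_hr_bpm"].to_numpy(float),
                                    df["duration_min"].to_numpy(float))


def write_plan(plan: TrainingPlan, path) -> None:
    df = pd.DataFrame({
        "day": np.arange(1, len(plan) + 1),
        "avg_hr_bpm": plan.avg_hrs,
        "duration_min": plan.durations,
    })
    df.to_csv(path, index=False)


def load_config(path) -> tuple[BanisterParameters, SwarmConfig, ConstraintConfig]:
    """Load a YAML config with optional banister/swarm/constraints sections.

    Section keys mirror the dataclass field names one-to-one; unknown
    keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = []
    for section, cls in [("banister", BanisterParameters),
                         ("swarm", SwarmConfig),
                         ("constraints", ConstraintConfig)]:
        kwargs = raw.get(section, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise PlanFormatError(
                f"{path}: unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
            )
        out.append(cls(**kwargs))
    return tuple(out)


@dataclass
class RunRecord:
    """Everything needed to reproduce and report one optimizer run."""

    seed: int
    athlete: AthleteProfile
    banister: BanisterParameters
    swarm: SwarmConfig
    constraints: ConstraintConfig
    plan: TrainingPlan
    report: ConstraintReport
    performance: PerformanceSeries
    trace: pd.DataFrame
    wall_time_s: float

    @property
    def final_performance(self) -> float:
        return float(self.performance.performance[-1])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "athlete": self.athlete.to_dict(),
            "banister": self.banister.to_dict(),
            "swarm": dataclasses.asdict(self.swarm),
            "constraints": dataclasses.asdict(self.constraints),
            "plan": {
                "avg_hr_bpm": list(self.plan.avg_hrs),
                "duration_min": list(self.plan.durations),
            },
            "report": self.report.to_dict(),
            "final_performance": self.final_performance,
            "wall_time_s": self.wall_time_s,
        }

    def to_json(self, path=None, **kw) -> str | None:
        text = json.dumps(self.to_dict(), **kw)
        if path is None:
            return text
        Path(path).write_text(text)
        return None


def _checkpoint_rows(trace: pd.DataFrame, n_particles: int,
                     checkpoints: Sequence[int]) -> dict[int, pd.Series]:
    """Trace rows at requested fitness-evaluation counts.

    Iteration r has consumed (r + 1) * N evaluations (the initial
    evaluation counts).  A checkpoint beyond the budget snaps to the
    final row.
    """
    rows = {}
    for fes in checkpoints:
        it = min(max(int(np.ceil(fes / n_particles)) - 1, 0), len(trace) - 1)
        rows[fes] = trace.iloc[it]
    return rows


def run_batch(athlete: AthleteProfile,
              params: BanisterParameters,
              swarm_cfg: SwarmConfig = SwarmConfig(),
              constraint_cfg: ConstraintConfig = ConstraintConfig(),
              n_runs: int = 30,
              base_seed: int = 0,
              checkpoints: Sequence[int] = (),
              progress: bool = False) -> tuple[list[RunRecord], pd.DataFrame]:
    """Independent optimizations with seeds base_seed .. base_seed+n-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records = []
    for k in range(n_runs):
        seed = base_seed + k
        t0 = time.perf_counter()
        res = optimize(athlete, params, swarm_cfg, constraint_cfg, seed=seed)
        rec = RunRecord(
            seed=seed, athlete=athlete, banister=params, swarm=swarm_cfg,
            constraints=constraint_cfg, plan=res.plan, report=res.report,
            performance=res.performance, trace=res.trace,
            wall_time_s=time.perf_counter() - t0,
        )
        records.append(rec)
        if progress:
            print(f"run {k + 1}/{n_runs} seed={seed} "
                  f"perf={rec.final_performance:.4f} "
                  f"phi={res.report.total_violation:.4g} "
                  f"({rec.wall_time_s:.1f}s)")
    summary = summarize_runs(records, checkpoints)
    return records, summary


def summarize_runs(records: Sequence[RunRecord],
                   checkpoints: Sequence[int] = ()) -> pd.DataFrame:
    """Best/worst/mean/sd table over runs, optionally at FE checkpoints.

    For performance "best" is the maximum; for violation metrics it is
    the minimum.
    """
    rows = []

    def add(metric, fes, values, maximize):
        values = np.asarray(values, dtype=float)
        rows.append({
            "metric": metric,
            "fes": fes,
            "best": float(values.max() if maximize else values.min()),
            "worst": float(values.min() if maximize else values.max()),
            "average": float(values.mean()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        })

    add("final_performance", "final",
        [r.final_performance for r in records], maximize=True)
    add("total_violation", "final",
        [r.report.total_violation for r in records], maximize=False)

    n = records[0].swarm.n_particles
    for fes in checkpoints:
        picked = [_checkpoint_rows(r.trace, n, [fes])[fes] for r in records]
        for metric in ("g_monotony", "g_ramp", "g_daily", "total_violation"):
            add(metric, fes, [p[metric] for p in picked], maximize=False)
    return pd.DataFrame(rows)
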