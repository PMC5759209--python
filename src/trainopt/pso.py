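"""Grouped, epsilon-constrained particle swarm optimizer.

Particles encode a whole plan as an interleaved vector
``HR1 D1 HR2 D2 ... HR56 D56`` (112 dimensions for an 8-week plan).
Candidates are ranked lexicographically: aggregate constraint
violation first (relaxed by the epsilon level), objective second.

The swarm is split into islands ("groups"); each particle is pulled
toward its personal best and its group's best.  Inertia decays
linearly over the run.  The per-dimension maximum velocity is adapted
downward whenever too few particles are feasible or the global best
stagnates, to reduce the chance of flying over the feasible region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constraints import ConstraintConfig, ConstraintReport, is_better, violations_from_loads
from .physiology import (
    AthleteProfile,
    BanisterParameters,
    PerformanceSeries,
    TrainingPlan,
    performance_series,
)

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "PlanProblem",
    "OptimizationResult",
    "encode",
    "decode",
    "initialize_swarm",
    "inertia_at",
    "step",
    "adapt_vmax",
    "run_pso",
    "optimize",
]

#: Default session-duration search bounds, minutes.
DURATION_BOUNDS = (30.0, 300.0)


@dataclass(frozen=True)
class SwarmConfig:
    """Hyper-parameters of the optimizer."""

    n_particles: int = 100
    n_groups: int = 4
    group_size: int = 25
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    max_iterations: int = 5000
    epsilon_level: float = 0.0
    feasible_fraction_weight: float = 0.2   # F_lambda
    update_threshold: float = 0.05          # F_theta
    vmax_shrink: float = 0.95               # gamma
    vmax_floor_frac: float = 1e-3
    vmax_adapt_period: int = 10             # iterations between adaptation checks
    global_social: bool = False             # pull toward global best instead of group best

    def __post_init__(self) -> None:
        if self.n_particles != self.n_groups * self.group_size:
            raise ValueError(
                f"n_particles ({self.n_particles}) must equal n_groups * "
                f"group_size ({self.n_groups} * {self.group_size})"
            )
        if not 0 < self.inertia_end <= self.inertia_start:
            raise ValueError("require 0 < inertia_end <= inertia_start")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


@dataclass
class SwarmState:
    """Mutable optimizer state (positions, bests, adaptive limits)."""

    positions: np.ndarray        # (N, D)
    velocities: np.ndarray       # (N, D)
    pbest_pos: np.ndarray        # (N, D)
    pbest_obj: np.ndarray        # (N,)
    pbest_phi: np.ndarray        # (N,)
    obj: np.ndarray              # (N,) current evaluation
    phi: np.ndarray              # (N,)
    vmax: np.ndarray             # (D,)
    bounds: np.ndarray           # (D, 2)
    iteration: int
    rng: np.random.Generator
    feasible_fraction: float = 0.0
    gbest_history: list = field(default_factory=list)   # (obj, phi) per iteration

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def group_best_indices(self, cfg: SwarmConfig) -> np.ndarray:
        """Index of the epsilon-best personal best within each group."""
        idx = np.empty(cfg.n_groups, dtype=int)
        for g in range(cfg.n_groups):
            lo = g * cfg.group_size
            members = range(lo, lo + cfg.group_size)
            best = lo
            for i in members:
                if is_better((self.pbest_obj[i], self.pbest_phi[i]),
                             (self.pbest_obj[best], self.pbest_phi[best]),
                             cfg.epsilon_level):
                    best = i
            idx[g] = best
        return idx

    def global_best_index(self, cfg: SwarmConfig) -> int:
        best = 0
        for i in range(1, self.n_particles):
            if is_better((self.pbest_obj[i], self.pbest_phi[i]),
                         (self.pbest_obj[best], self.pbest_phi[best]),
                         cfg.epsilon_level):
                best = i
        return best


def encode(plan: TrainingPlan) -> np.ndarray:
    """Plan -> interleaved (HR, duration) decision vector."""
    out = np.empty(2 * len(plan))
    out[0::2] = plan.avg_hrs
    out[1::2] = plan.durations
    return out


def decode(position: Sequence[float]) -> TrainingPlan:
    """Interleaved decision vector -> plan."""
    position = np.asarray(position, dtype=float)
    if position.ndim != 1 or position.size % 2:
        raise ValueError(f"position must be a flat even-length vector, got shape {position.shape}")
    return TrainingPlan.from_arrays(position[0::2], position[1::2])


def plan_bounds(athlete: AthleteProfile, n_sessions: int = 56,
                duration_bounds: tuple[float, float] = DURATION_BOUNDS) -> np.ndarray:
    """Per-dimension [low, high] for the interleaved plan vector."""
    b = np.empty((2 * n_sessions, 2))
    b[0::2] = (athlete.resting_hr, athlete.max_hr)
    b[1::2] = duration_bounds
    return b


class PlanProblem:
    """Batched objective/violation evaluation of plan decision vectors."""

    def __init__(self, athlete: AthleteProfile, params: BanisterParameters,
                 constraint_cfg: ConstraintConfig = ConstraintConfig(),
                 n_sessions: int = 56,
                 duration_bounds: tuple[float, float] = DURATION_BOUNDS,
                 objective: str = "final"):
        self.athlete = athlete
        self.params = params
        self.ccfg = constraint_cfg
        self.n_sessions = n_sessions
        self.bounds = plan_bounds(athlete, n_sessions, duration_bounds)
        if objective not in ("final", "max"):
            raise ValueError(f"unknown objective {objective!r}")
        self.objective = objective
        M = n_sessions
        i = np.arange(M)  # session j trains on day i = j
        self._w_fit = params.k1 * np.exp(-(M - i) / params.r1)
        self._w_fat = params.k2 * np.exp(-(M - i) / params.r2)
        if objective == "max":
            # K[i, t-1] = net response on day t to a unit load on day i (i < t)
            lag = np.arange(1, M + 1)[None, :] - i[:, None]
            K = np.where(lag > 0,
                         params.k1 * np.exp(-lag / params.r1)
                         - params.k2 * np.exp(-lag / params.r2), 0.0)
            self._kernel = K

    def loads(self, positions: np.ndarray) -> np.ndarray:
        """Daily TRIMP matrix (N, M) for a batch of positions."""
        hr = positions[:, 0::2]
        dur = positions[:, 1::2]
        a = self.athlete
        nh = np.clip((hr - a.resting_hr) / a.hr_range, 0.0, 1.0)
        return dur * nh * np.exp(a.sex_factor_y * nh)

    def __call__(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        positions = np.atleast_2d(positions)
        w = self.loads(positions)
        p0 = self.athlete.baseline_performance_p0
        if self.objective == "max":
            obj = p0 + (w @ self._kernel).max(axis=1)
        else:
            obj = p0 + w @ self._w_fit - w @ self._w_fat
        phi = self._phi(w)
        return obj, phi

    def _phi(self, w: np.ndarray) -> np.ndarray:
        cfg = self.ccfg
        N, M = w.shape
        wl = cfg.week_length
        n_weeks = M // wl
        weeks = w[:, : n_weeks * wl].reshape(N, n_weeks, wl)
        mean = weeks.mean(axis=2)
        sd = weeks.std(axis=2, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mono = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
        mono[mean == 0] = 0.0
        mono_excess = np.maximum(0.0, mono - cfg.monotony_max) / cfg.monotony_max
        mono_excess = np.where(np.isinf(mono_excess),
                               cfg.infinite_monotony_penalty, mono_excess)

        tau = cfg.ctl_time_constant
        ctl = np.full(N, cfg.ctl_start)
        week_end_ctl = np.empty((N, n_weeks))
        k = 0
        for d in range(M):
            ctl = ctl + (w[:, d] - ctl) / tau
            if (d + 1) % wl == 0 and k < n_weeks:
                week_end_ctl[:, k] = ctl
                k += 1
        ramps = np.diff(np.concatenate(
            [np.full((N, 1), cfg.ctl_start), week_end_ctl], axis=1), axis=1)
        ramp_excess = np.maximum(0.0, ramps - cfg.ramp_rate_max) / cfg.ramp_rate_max

        daily_excess = np.maximum(0.0, w - cfg.daily_trimp_max) / cfg.daily_trimp_max

        if cfg.aggregate == "max":
            g1, g2, g3 = (mono_excess.max(axis=1), ramp_excess.max(axis=1),
                          daily_excess.max(axis=1))
        else:
            g1, g2, g3 = (mono_excess.sum(axis=1), ramp_excess.sum(axis=1),
                          daily_excess.sum(axis=1))
        p = cfg.violation_exponent
        return g1 ** p + g2 ** p + g3 ** p


def initialize_swarm(bounds: np.ndarray, cfg: SwarmConfig,
                     seed: int | np.random.Generator | None = None) -> SwarmState:
    """Uniform random positions within bounds, zero velocities, full-range Vmax."""
    bounds = np.asarray(bounds, dtype=float)
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        bad = int(np.argmax(bounds[:, 0] >= bounds[:, 1]))
        raise ValueError(f"bounds[{bad}]: low {bounds[bad, 0]} >= high {bounds[bad, 1]}")
    rng = np.random.default_rng(seed)
    D = bounds.shape[0]
    pos = rng.uniform(bounds[:, 0], bounds[:, 1], size=(cfg.n_particles, D))
    return SwarmState(
        positions=pos,
        velocities=np.zeros_like(pos),
        pbest_pos=pos.copy(),
        pbest_obj=np.full(cfg.n_particles, -np.inf),
        pbest_phi=np.full(cfg.n_particles, np.inf),
        obj=np.full(cfg.n_particles, -np.inf),
        phi=np.full(cfg.n_particles, np.inf),
        vmax=bounds[:, 1] - bounds[:, 0],
        bounds=bounds,
        iteration=0,
        rng=rng,
    )


def inertia_at(iteration: int, cfg: SwarmConfig) -> float:
    """Linearly decaying inertia weight: w0 at r=0, wT at r=T."""
    T = max(cfg.max_iterations, 1)
    frac = min(max(iteration, 0), T) / T
    return cfg.inertia_start + (cfg.inertia_end - cfg.inertia_start) * frac


def _evaluate_into(state: SwarmState, evaluate: Callable, cfg: SwarmConfig) -> None:
    """Evaluate current positions, tolerate failures, update personal bests."""
    try:
        obj, phi = evaluate(state.positions)
        obj = np.asarray(obj, dtype=float)
        phi = np.asarray(phi, dtype=float)
    except Exception:
        obj = np.empty(state.n_particles)
        phi = np.empty(state.n_particles)
        for i in range(state.n_particles):
            try:
                o, f = evaluate(state.positions[i : i + 1])
                obj[i], phi[i] = float(np.ravel(o)[0]), float(np.ravel(f)[0])
            except Exception:
                obj[i], phi[i] = -np.inf, np.inf
    bad = ~(np.isfinite(obj) | np.isneginf(obj)) | np.isnan(phi)
    obj[bad] = -np.inf
    phi[bad] = np.inf
    state.obj, state.phi = obj, phi

    eps = cfg.epsilon_level
    ephi_new = np.where(phi <= eps, 0.0, phi)
    ephi_old = np.where(state.pbest_phi <= eps, 0.0, state.pbest_phi)
    better = (ephi_new < ephi_old) | ((ephi_new == ephi_old) & (obj > state.pbest_obj))
    state.pbest_pos[better] = state.positions[better]
    state.pbest_obj[better] = obj[better]
    state.pbest_phi[better] = phi[better]

    state.feasible_fraction = float(np.mean(phi <= eps))
    gi = state.global_best_index(cfg)
    state.gbest_history.append((state.pbest_obj[gi], state.pbest_phi[gi]))


def step(state: SwarmState, evaluate: Callable, cfg: SwarmConfig) -> SwarmState:
    """One synchronous PSO iteration (velocity/position update + evaluation)."""
    N, D = state.positions.shape
    if cfg.global_social:
        gi = state.global_best_index(cfg)
        social_target = np.broadcast_to(state.pbest_pos[gi], (N, D))
    else:
        gidx = state.group_best_indices(cfg)
        per_particle = np.repeat(gidx, cfg.group_size)
        social_target = state.pbest_pos[per_particle]

    w = inertia_at(state.iteration, cfg)
    r1 = state.rng.uniform(size=(N, D))
    r2 = state.rng.uniform(size=(N, D))
    vel = (w * state.velocities
           + cfg.c1 * r1 * (state.pbest_pos - state.positions)
           + cfg.c2 * r2 * (social_target - state.positions))
    vel = np.clip(vel, -state.vmax, state.vmax)

    pos = state.positions + vel
    lo, hi = state.bounds[:, 0], state.bounds[:, 1]
    clamped = (pos < lo) | (pos > hi)
    pos = np.clip(pos, lo, hi)
    vel[clamped] = 0.0  # kill momentum on the wall

    state.positions = pos
    state.velocities = vel
    state.iteration += 1
    _evaluate_into(state, evaluate, cfg)
    return state


def adapt_vmax(state: SwarmState, cfg: SwarmConfig) -> SwarmState:
    """Shrink per-dimension Vmax when feasibility or progress is lacking.

    Checked every ``vmax_adapt_period`` iterations: if the feasible
    fraction is below F_lambda, or the global best objective improved
    by less than the relative tolerance F_theta over the window, every
    Vmax component is multiplied by ``vmax_shrink``, floored at
    ``vmax_floor_frac`` of the dimension range.
    """
    period = max(cfg.vmax_adapt_period, 1)
    if state.iteration == 0 or state.iteration % period:
        return state
    shrink = state.feasible_fraction < cfg.feasible_fraction_weight
    if not shrink and len(state.gbest_history) > period:
        now_obj, now_phi = state.gbest_history[-1]
        then_obj, then_phi = state.gbest_history[-1 - period]
        gain = now_obj - then_obj
        phi_gain = then_phi - now_phi
        rel = gain / max(1.0, abs(then_obj))
        shrink = rel < cfg.update_threshold and phi_gain <= 0
    if shrink:
        floor = cfg.vmax_floor_frac * (state.bounds[:, 1] - state.bounds[:, 0])
        state.vmax = np.maximum(state.vmax * cfg.vmax_shrink, floor)
    return state


@dataclass
class OptimizationResult:
    plan: TrainingPlan
    performance: PerformanceSeries
    report: ConstraintReport
    trace: pd.DataFrame
    best_objective: float
    best_violation: float
    state: SwarmState


def run_pso(evaluate: Callable, bounds: np.ndarray, cfg: SwarmConfig,
            seed: int | None = None,
            trace_extra: Callable | None = None) -> tuple[np.ndarray, float, float, pd.DataFrame, SwarmState]:
    """Generic driver: returns (best position, best obj, best phi, trace, state)."""
    state = initialize_swarm(bounds, cfg, seed)
    _evaluate_into(state, evaluate, cfg)
    rows = []

    def record():
        gi = state.global_best_index(cfg)
        row = {
            "iteration": state.iteration,
            "best_objective": state.pbest_obj[gi],
            "total_violation": state.pbest_phi[gi],
            "feasible_fraction": state.feasible_fraction,
            "vmax_mean": float(state.vmax.mean()),
        }
        if trace_extra is not None:
            row.update(trace_extra(state.pbest_pos[gi]))
        rows.append(row)

    record()
    for _ in range(cfg.max_iterations):
        step(state, evaluate, cfg)
        adapt_vmax(state, cfg)
        record()
    gi = state.global_best_index(cfg)
    trace = pd.DataFrame(rows)
    return (state.pbest_pos[gi].copy(), float(state.pbest_obj[gi]),
            float(state.pbest_phi[gi]), trace, state)


def optimize(athlete: AthleteProfile, params: BanisterParameters,
             cfg: SwarmConfig = SwarmConfig(),
             constraint_cfg: ConstraintConfig = ConstraintConfig(),
             seed: int | None = None,
             n_sessions: int = 56,
             duration_bounds: tuple[float, float] = DURATION_BOUNDS) -> OptimizationResult:
    """Search the plan space; return the best plan with full diagnostics."""
    problem = PlanProblem(athlete, params, constraint_cfg, n_sessions, duration_bounds)

    def extra(best_pos: np.ndarray) -> dict:
        rep = violations_from_loads(problem.loads(best_pos[None, :])[0], constraint_cfg)
        return {"g_monotony": rep.g_monotony, "g_ramp": rep.g_ramp,
                "g_daily": rep.g_daily}

    best_pos, best_obj, best_phi, trace, state = run_pso(
        problem, problem.bounds, cfg, seed, trace_extra=extra)
    plan = decode(best_pos)
    series = performance_series(plan, athlete, params)
    report = violations_from_loads(series.loads, constraint_cfg)
    trace = trace.rename(columns={"best_objective": "best_performance"})
    return OptimizationResult(
        plan=plan,
        performance=series,
        report=report,
        trace=trace,
        best_objective=best_obj,
        best_violation=best_phi,
        state=state,
    )
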