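import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trainopt import (
    BanisterParameters,
    ConstraintConfig,
    SwarmConfig,
    decode,
    encode,
    inertia_at,
    initialize_swarm,
    optimize,
    run_pso,
    simulated_athlete,
)
from trainopt.pso import PlanProblem, adapt_vmax, plan_bounds, step

SMALL = SwarmConfig(n_particles=20, n_groups=4, group_size=5, max_iterations=50)
BOUNDS_2D = np.array([[-2.0, 2.0], [-2.0, 2.0]])


def toy_eval(positions):
    """max sum(x) s.t. sum(x) <= 1; violation normalized and squared."""
    s = positions.sum(axis=1)
    return s, np.maximum(0.0, s - 1.0) ** 2


def sphere_eval(positions):
    return -(positions ** 2).sum(axis=1), np.zeros(len(positions))


class TestCodec:
    def test_single_session(self):
        plan = decode([120.0, 60.0])
        assert len(plan) == 1
        assert plan[0].avg_hr == 120 and plan[0].duration_min == 60

    def test_112_vector_gives_56_sessions(self, rng):
        x = rng.uniform(30, 200, 112)
        assert len(decode(x)) == 56

    def test_roundtrip(self, rng):
        x = rng.uniform(30, 200, 112)
        assert np.array_equal(encode(decode(x)), x)

    def test_interleaving(self):
        plan = decode([100.0, 30.0, 150.0, 90.0])
        assert [s.avg_hr for s in plan] == [100, 150]
        assert [s.duration_min for s in plan] == [30, 90]

    def test_odd_length_raises(self):
        with pytest.raises(ValueError):
            decode([1.0, 2.0, 3.0])


class TestSwarmConfig:
    def test_group_product_enforced(self):
        with pytest.raises(ValueError):
            SwarmConfig(n_particles=100, n_groups=4, group_size=30)

    def test_defaults_consistent(self):
        cfg = SwarmConfig()
        assert cfg.n_particles == cfg.n_groups * cfg.group_size == 100


class TestInitializeSwarm:
    def test_deterministic(self):
        s1 = initialize_swarm(BOUNDS_2D, SMALL, seed=42)
        s2 = initialize_swarm(BOUNDS_2D, SMALL, seed=42)
        assert np.array_equal(s1.positions, s2.positions)

    def test_velocities_zero_and_vmax_full_range(self):
        s = initialize_swarm(BOUNDS_2D, SMALL, seed=0)
        assert np.all(s.velocities == 0)
        assert np.allclose(s.vmax, 4.0)

    def test_positions_within_bounds(self, athlete):
        b = plan_bounds(athlete)
        assert b.shape == (112, 2)
        s = initialize_swarm(b, SMALL, seed=1)
        assert s.positions.shape == (20, 112)
        assert np.all(s.positions[:, 0::2] >= 51) and np.all(s.positions[:, 0::2] <= 189)
        assert np.all(s.positions[:, 1::2] >= 30) and np.all(s.positions[:, 1::2] <= 300)

    def test_bad_bounds_raise(self):
        with pytest.raises(ValueError, match="bounds"):
            initialize_swarm(np.array([[1.0, 1.0]]), SMALL)


class TestInertia:
    def test_endpoints(self):
        cfg = SwarmConfig(max_iterations=1000)
        assert inertia_at(0, cfg) == pytest.approx(0.9)
        assert inertia_at(1000, cfg) == pytest.approx(0.4)

    def test_midpoint(self):
        cfg = SwarmConfig(max_iterations=1000)
        assert inertia_at(500, cfg) == pytest.approx(0.65)


class TestStep:
    def test_fixed_point_without_attraction(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=10, c1=0.0, c2=0.0)
        s = initialize_swarm(BOUNDS_2D, cfg, seed=0)
        s.positions[:] = 0.5
        from trainopt.pso import _evaluate_into
        _evaluate_into(s, toy_eval, cfg)
        pos_before = s.positions.copy()
        step(s, toy_eval, cfg)
        assert np.array_equal(s.positions, pos_before)

    def test_velocity_clamped_to_vmax(self):
        s = initialize_swarm(BOUNDS_2D, SMALL, seed=3)
        from trainopt.pso import _evaluate_into
        _evaluate_into(s, toy_eval, SMALL)
        s.vmax[:] = 0.01
        step(s, toy_eval, SMALL)
        assert np.all(np.abs(s.velocities) <= 0.01 + 1e-15)

    def test_positions_stay_in_bounds(self):
        s = initialize_swarm(BOUNDS_2D, SMALL, seed=4)
        from trainopt.pso import _evaluate_into
        _evaluate_into(s, toy_eval, SMALL)
        for _ in range(20):
            step(s, toy_eval, SMALL)
            assert np.all(s.positions >= -2) and np.all(s.positions <= 2)

    def test_feasible_newcomer_becomes_global_best(self):
        cfg = SMALL
        s = initialize_swarm(BOUNDS_2D, cfg, seed=5)
        # force all personal bests infeasible with high objective
        s.pbest_obj[:] = 100.0
        s.pbest_phi[:] = 4.0
        s.positions[:] = 0.0  # sum 0 -> feasible, objective 0
        from trainopt.pso import _evaluate_into
        _evaluate_into(s, toy_eval, cfg)
        gi = s.global_best_index(cfg)
        assert s.pbest_phi[gi] == 0.0

    def test_evaluation_failure_assigns_worst(self):
        cfg = SMALL
        s = initialize_swarm(BOUNDS_2D, cfg, seed=6)

        def flaky(positions):
            if positions.shape[0] > 1:
                raise RuntimeError("batch failure")
            if positions[0, 0] > 0:
                raise RuntimeError("particle failure")
            return toy_eval(positions)

        from trainopt.pso import _evaluate_into
        _evaluate_into(s, flaky, cfg)
        broken = s.positions[:, 0] > 0
        assert np.all(s.obj[broken] == -np.inf)
        assert np.all(np.isinf(s.phi[broken]))
        assert np.any(np.isfinite(s.obj[~broken]))


class TestAdaptVmax:
    def test_low_feasible_fraction_shrinks(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=100, vmax_adapt_period=1)
        s = initialize_swarm(BOUNDS_2D, cfg, seed=0)
        s.iteration = 1
        s.feasible_fraction = 0.0
        before = s.vmax.copy()
        adapt_vmax(s, cfg)
        assert np.allclose(s.vmax, before * cfg.vmax_shrink)

    def test_no_trigger_no_change(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=100, vmax_adapt_period=1)
        s = initialize_swarm(BOUNDS_2D, cfg, seed=0)
        s.iteration = 5
        s.feasible_fraction = 1.0
        s.gbest_history = [(0.0, 0.0), (10.0, 0.0)]  # improving fast
        before = s.vmax.copy()
        adapt_vmax(s, cfg)
        assert np.array_equal(s.vmax, before)

    def test_floor_respected(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=100, vmax_adapt_period=1)
        s = initialize_swarm(BOUNDS_2D, cfg, seed=0)
        s.feasible_fraction = 0.0
        for it in range(1, 500):
            s.iteration = it
            adapt_vmax(s, cfg)
        floor = cfg.vmax_floor_frac * 4.0
        assert np.all(s.vmax >= floor - 1e-15)
        assert np.allclose(s.vmax, floor)


class TestRunPso:
    def test_zero_iterations_returns_initial_best(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=0)
        pos, obj, phi, trace, state = run_pso(toy_eval, BOUNDS_2D, cfg, seed=7)
        assert len(trace) == 1
        o, p = toy_eval(pos[None, :])
        assert obj == pytest.approx(float(o[0]))

    def test_seed_determinism_bit_identical(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=40)
        r1 = run_pso(toy_eval, BOUNDS_2D, cfg, seed=11)
        r2 = run_pso(toy_eval, BOUNDS_2D, cfg, seed=11)
        assert np.array_equal(r1[0], r2[0])
        assert r1[3].equals(r2[3])

    def test_elitism_monotone_trace(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=60)
        _, _, _, trace, _ = run_pso(toy_eval, BOUNDS_2D, cfg, seed=2)
        phi = trace["total_violation"].to_numpy()
        obj = trace["best_objective"].to_numpy()
        for i in range(1, len(trace)):
            assert (phi[i] < phi[i - 1]
                    or (phi[i] == phi[i - 1] and obj[i] >= obj[i - 1]))

    def test_sphere_monotone_improvement(self):
        cfg = SwarmConfig(max_iterations=100)
        bounds = np.tile([[-5.0, 5.0]], (112, 1))
        _, obj, phi, trace, _ = run_pso(sphere_eval, bounds, cfg, seed=0)
        best = trace["best_objective"].to_numpy()
        assert np.all(np.diff(best) >= 0)
        assert best[-1] > best[0]

    def test_toy_problem_convergence(self):
        cfg = SwarmConfig(max_iterations=500)
        _, obj, phi, _, _ = run_pso(toy_eval, BOUNDS_2D, cfg, seed=0)
        assert phi <= 1e-6
        assert obj == pytest.approx(1.0, rel=0.01)

    def test_global_social_variant_runs(self):
        cfg = SwarmConfig(n_particles=20, n_groups=4, group_size=5,
                          max_iterations=100, global_social=True)
        _, obj, phi, _, _ = run_pso(toy_eval, BOUNDS_2D, cfg, seed=0)
        assert phi <= 1e-4


class TestPlanProblem:
    def test_batch_matches_scalar_path(self, athlete, params, rng):
        from trainopt import performance_series, trimp_series, violations
        problem = PlanProblem(athlete, params)
        pos = rng.uniform(problem.bounds[:, 0], problem.bounds[:, 1], (5, 112))
        obj, phi = problem(pos)
        for i in range(5):
            plan = decode(pos[i])
            series = performance_series(plan, athlete, params)
            from trainopt.constraints import violations_from_loads
            rep = violations_from_loads(series.loads)
            assert obj[i] == pytest.approx(series.performance[-1], abs=1e-9)
            assert phi[i] == pytest.approx(rep.total_violation, abs=1e-9)

    def test_max_objective_upper_bounds_final(self, athlete, params, rng):
        pf = PlanProblem(athlete, params, objective="final")
        pm = PlanProblem(athlete, params, objective="max")
        pos = rng.uniform(pf.bounds[:, 0], pf.bounds[:, 1], (5, 112))
        assert np.all(pm(pos)[0] >= pf(pos)[0] - 1e-9)


@pytest.fixture(scope="module")
def result():
    return optimize(simulated_athlete(), BanisterParameters(),
                    SwarmConfig(max_iterations=200), seed=0)


class TestOptimizePlan:
    def test_plan_respects_bounds(self, result):
        hrs = result.plan.avg_hrs
        durs = result.plan.durations
        assert np.all(hrs >= 51) and np.all(hrs <= 189)
        assert np.all(durs >= 30) and np.all(durs <= 300)

    def test_plan_length(self, result):
        assert len(result.plan) == 56

    def test_trace_columns(self, result):
        for col in ("iteration", "best_performance", "total_violation",
                    "g_monotony", "g_ramp", "g_daily"):
            assert col in result.trace.columns

    def test_report_matches_plan(self, result):
        from trainopt import violations
        rep = violations(result.plan, simulated_athlete())
        assert rep.total_violation == pytest.approx(result.report.total_violation)

    def test_objective_matches_series(self, result):
        assert result.best_objective == pytest.approx(
            float(result.performance.performance[-1]), abs=1e-9)
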