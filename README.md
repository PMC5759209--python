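# trainopt

Constraint-aware cycling training-plan optimization.

`trainopt` builds an 8-week (56-session) training plan — one average
heart rate and duration per day — that maximizes final-day athletic
performance under the Banister fitness–fatigue impulse-response model,
while honouring three physiological safety constraints:

1. **weekly training monotony** (mean daily TRIMP / sd of daily TRIMP
   per 7-day block) ≤ 1.5,
2. **chronic-training-load ramp rate** (week-over-week change of the
   42-day EWMA of daily TRIMP) ≤ 5 TRIMP/day per week,
3. **daily TRIMP** ≤ 450.

The search engine is a grouped, ε-constrained particle swarm
optimizer: candidates are ordered by aggregate constraint violation
first (squared sum of threshold-normalized excesses), objective
second; inertia decays linearly and the per-dimension maximum
velocity shrinks adaptively when feasibility or progress stalls.

A synthetic "coached standard" plan generator and a dynamic-time-warping
similarity measure support plan comparisons.

## CLI

```bash
# optimize a plan for the built-in simulated athlete
trainopt optimize --seed 7 --iterations 500 --out plan.csv --trace trace.csv

# evaluate an existing plan CSV (day,avg_hr_bpm,duration_min)
trainopt evaluate plan.csv --json

# generate the feasible synthetic benchmark plan
trainopt synth-benchmark --out standard.csv

# compare two plans: performance series + DTW similarity
trainopt compare plan.csv standard.csv --plot compare.png

# 30 independent runs with a best/worst/average/sd summary
trainopt batch --runs 30 --seed 0 --checkpoints 50,500,50000 --out summary.csv
```

Athlete profiles are JSON
(`{"resting_hr": 51, "max_hr": 189, "fthr": 165, "sex": "male", "p0": 0.0}`);
optimizer/physiology settings live in a YAML file with `banister`,
`swarm` and `constraints` sections whose keys mirror the dataclass
fields 1:1 (see `trainopt.planio.load_config`).

Banister model constants default to a published fit
(k1 = 0.031, k2 = 0.087, r1 = 30.8 d, r2 = 16.8 d) and are always
echoed in run output; override them in the YAML config for a specific
athlete.

## Package layout

| module | contents |
|---|---|
| `trainopt.physiology` | athlete/plan/parameter types, normalized HR, TRIMP, Banister performance, FTHR-anchored heart-rate zones |
| `trainopt.constraints` | monotony, CTL, ramp rates, violation report, ε-comparison |
| `trainopt.pso` | particle codec, swarm state, adaptive ε-constrained PSO |
| `trainopt.benchmark` | synthetic standard plan, DTW distance/similarity |
| `trainopt.planio` | plan/trace CSV, YAML config, run records, batch runs |
| `trainopt.cli` | `trainopt` command-line entry points |
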