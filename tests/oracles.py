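"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity in the most literal way
possible (double loops, explicit path enumeration, closed forms) and
must stay independent of the implementations they check.
"""

import math
from functools import lru_cache

import numpy as np


def banister_performance_naive(loads, p0, k1, k2, r1, r2, t):
    """Literal double-loop evaluation: session j (1-based) is day i = j - 1."""
    fit = sum(w * math.exp(-(t - i) / r1) for i, w in enumerate(loads[:t]))
    fat = sum(w * math.exp(-(t - i) / r2) for i, w in enumerate(loads[:t]))
    return p0 + k1 * fit - k2 * fat


def trimp_naive(duration, avg_hr, resting, mx, y):
    nh = (avg_hr - resting) / (mx - resting)
    return duration * nh * math.exp(y * nh)


def monotony_naive(week):
    """Mean over sample standard deviation, by-hand arithmetic."""
    n = len(week)
    mean = sum(week) / n
    if mean == 0:
        return 0.0
    var = sum((x - mean) ** 2 for x in week) / (n - 1)
    if var == 0:
        return math.inf
    return mean / math.sqrt(var)


def ctl_constant_closed_form(load, tau, t):
    """CTL after t days of constant load starting from 0."""
    return load * (1.0 - ((tau - 1.0) / tau) ** t)


@lru_cache(maxsize=None)
def warping_paths(n: int, m: int):
    """All monotone step-{(1,0),(0,1),(1,1)} paths from (0,0) to (n-1,m-1)."""
    if n == 1 and m == 1:
        return [((0, 0),)]
    paths = []
    if n > 1:
        paths += [p + ((n - 1, m - 1),) for p in warping_paths(n - 1, m)]
    if m > 1:
        paths += [p + ((n - 1, m - 1),) for p in warping_paths(n, m - 1)]
    if n > 1 and m > 1:
        paths += [p + ((n - 1, m - 1),) for p in warping_paths(n - 1, m - 1)]
    return paths


def dtw_exhaustive(a, b):
    """Minimum |x-y| path cost over every explicit warping path."""
    best = math.inf
    for path in warping_paths(len(a), len(b)):
        cost = sum(abs(a[i] - b[j]) for i, j in path)
        best = min(best, cost)
    return best


def feasible_naive(loads, monotony_max=1.5, ramp_max=5.0, daily_max=450.0,
                   tau=42.0, week=7):
    """Direct yes/no feasibility check of a daily load series."""
    loads = list(loads)
    n_weeks = len(loads) // week
    for k in range(n_weeks):
        m = monotony_naive(loads[k * week:(k + 1) * week])
        if m > monotony_max:
            return False
    ctl, prev_week_ctl = 0.0, 0.0
    for d, w in enumerate(loads):
        ctl += (w - ctl) / tau
        if (d + 1) % week == 0 and (d + 1) // week <= n_weeks:
            if ctl - prev_week_ctl > ramp_max:
                return False
            prev_week_ctl = ctl
    return all(w <= daily_max for w in loads)
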