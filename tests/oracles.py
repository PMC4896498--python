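"""Independent brute-force oracles used to pin down the estimators.

These deliberately re-derive each quantity with the most literal possible
algorithm (explicit loops, grid search, exhaustive enumeration) so they share
no code with the implementations they check.
"""

from __future__ import annotations

import statistics

import numpy as np


def bh_stepup(pvalues, alpha=0.05):
    """Benjamini-Hochberg by the literal step-up rule; returns reject flags."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k = 0
    for rank, i in enumerate(order, start=1):
        if pvalues[i] <= alpha * rank / m:
            k = rank
    reject = [False] * m
    for i in order[:k]:
        reject[i] = True
    return reject


def bh_adjusted(pvalues):
    """BH-adjusted p-values: running minimum of m*p_(j)/j from the largest."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adj[i] = running
    return adj


def passing_bablok(x, y):
    """Exhaustive pairwise-slope Passing-Bablok with the classical K offset."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0:
                continue  # undefined slope
            s = dy / dx
            if s == -1.0:
                continue
            slopes.append(s)
    slopes.sort()
    n_s = len(slopes)
    k_off = sum(1 for s in slopes if s < -1.0)
    if n_s % 2:
        slope = slopes[(n_s - 1) // 2 + k_off]
    else:
        slope = 0.5 * (slopes[n_s // 2 - 1 + k_off] + slopes[n_s // 2 + k_off])
    intercept = statistics.median(yi - slope * xi for xi, yi in zip(x, y))
    return intercept, slope


def deming_grid(x, y, span=5.0, rounds=6, n_grid=201):
    """Orthogonal regression by shrinking grid search over the slope.

    For a fixed slope b the optimal intercept is mean(y) - b*mean(x); the
    perpendicular squared distance sum (y - a - b*x)^2 / (1 + b^2) is then
    minimized over b by iterative grid refinement.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def cost(b):
        a = y.mean() - b * x.mean()
        return np.sum((y - a - b * x) ** 2) / (1.0 + b ** 2)

    lo, hi = -span, span
    best = 0.0
    for _ in range(rounds):
        grid = np.linspace(lo, hi, n_grid)
        costs = [cost(b) for b in grid]
        best = grid[int(np.argmin(costs))]
        step = (hi - lo) / (n_grid - 1)
        lo, hi = best - 2 * step, best + 2 * step
    a = y.mean() - best * x.mean()
    return float(a), float(best)
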