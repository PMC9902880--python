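"""Independent reference implementations used only as test oracles."""

import itertools

import numpy as np


def exhaustive_segmentation(y, beta, min_size=2):
    """Brute-force optimal piecewise-constant segmentation.

    Minimizes total within-segment SSE + beta·(number of change points) over
    *all* subsets of admissible change points; tractable only for short
    traces (n ≤ ~14).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    best_cost, best_cps = None, []
    for k in range(0, n):
        any_valid = False
        for cps in itertools.combinations(range(min_size, n - min_size + 1), k):
            bounds = [0, *cps, n]
            if any(b - a < min_size for a, b in zip(bounds, bounds[1:])):
                continue
            any_valid = True
            cost = sum(
                float(np.sum((y[a:b] - y[a:b].mean()) ** 2))
                for a, b in zip(bounds, bounds[1:])
            ) + beta * k
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best_cps = cost, list(cps)
        if not any_valid:
            break
    return best_cps


def ols_normal_equations(x, y):
    """Closed-form OLS oracle via the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    return slope, intercept
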