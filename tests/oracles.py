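"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the SVM oracle solves
the primal soft-margin quadratic program with a generic NLP solver, the
clustering oracle enumerates every bipartition, and the border-angle oracle
is a rotation search over line directions.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def qp_svm(X: np.ndarray, y: np.ndarray, cost: float = 1.0):
    """Solve min 0.5||w||^2 + C sum(xi) s.t. y_i(w.x_i+b) >= 1-xi_i, xi >= 0.

    Returns (w, b, xi).  Suitable only for small problems.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1:]

    def objective(z):
        w, _, xi = unpack(z)
        return 0.5 * float(w @ w) + cost * float(xi.sum())

    def grad(z):
        w, _, xi = unpack(z)
        g = np.zeros_like(z)
        g[:d] = w
        g[d + 1:] = cost
        return g

    constraints = [{
        "type": "ineq",
        "fun": lambda z, i=i: y[i] * (X[i] @ z[:d] + z[d]) - 1.0 + z[d + 1 + i],
    } for i in range(n)]
    bounds = [(None, None)] * (d + 1) + [(0.0, None)] * n
    z0 = np.zeros(d + 1 + n)
    z0[d + 1:] = 1.0
    res = minimize(objective, z0, jac=grad, method="SLSQP", bounds=bounds,
                   constraints=constraints,
                   options={"maxiter": 1000, "ftol": 1e-12})
    assert res.success, res.message
    w, b, xi = unpack(res.x)
    return w, float(b), np.maximum(xi, 0.0)


def brute_force_two_means(X: np.ndarray, squared: bool = True):
    """Global optimum over all nontrivial bipartitions (centroid = mean)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    best_cost, best_mask = np.inf, None
    for bits in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        cost = 0.0
        for part in (X[mask], X[~mask]):
            if len(part) == 0:
                continue
            mu = part.mean(axis=0)
            d2 = ((part - mu) ** 2).sum(axis=1)
            cost += float(d2.sum() if squared else np.sqrt(d2).sum())
        if cost < best_cost:
            best_cost, best_mask = cost, mask
    return best_mask, best_cost


def rotation_search_angle(w: np.ndarray, b_unused: float, axis_index: int,
                          axis_scales) -> float:
    """Border angle via brute-force search over line directions.

    Scans directions d(theta) in the rescaled plane for the one lying in the
    hyperplane (w' . d = 0) and returns its acute angle to the given axis.
    """
    scales = np.asarray(axis_scales, dtype=float)
    w_prime = np.asarray(w, dtype=float) / scales
    thetas = np.arange(0.0, 180.0, 0.001)
    dirs = np.stack([np.cos(np.radians(thetas)), np.sin(np.radians(thetas))], axis=1)
    residual = np.abs(dirs @ w_prime)
    d = dirs[int(np.argmin(residual))]
    cosang = abs(d[axis_index]) / np.linalg.norm(d)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
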