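"""Independent oracles used by the test suite.

Everything here is deliberately coded by a different route than the
package: dense SLSQP for the SVR dual, normal equations for least squares,
explicit loops for BH and leave-one-out, exhaustive hypergeometric
enumeration for Fisher's exact test. These never call into epiclock's
implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def rbf_gram(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = math.exp(-gamma * float(((A[i] - B[j]) ** 2).sum()))
    return out


def svr_dual_qp_oracle(X: np.ndarray, y: np.ndarray, C: float, gamma: float, eps: float):
    """Solve the 2n-variable SVR dual with dense SLSQP.

    Returns (objective, beta, bias, predict_fn).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = y.size
    K = rbf_gram(X, X, gamma)
    s = np.concatenate([np.ones(n), -np.ones(n)])
    p = np.concatenate([eps - y, eps + y])
    Q = np.block([[K, -K], [-K, K]])

    def fun(z):
        return 0.5 * z @ Q @ z + p @ z

    def jac(z):
        return Q @ z + p

    res = minimize(
        fun,
        np.zeros(2 * n),
        jac=jac,
        hess=lambda z: Q,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[LinearConstraint(s, 0.0, 0.0)],
        method="trust-constr",
        options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
    )
    # polish with SLSQP from the interior-point solution (active set is now
    # nearly correct, so the line search no longer stalls)
    polished = minimize(
        fun,
        np.clip(res.x, 0.0, C),
        jac=jac,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[{"type": "eq", "fun": lambda z: s @ z, "jac": lambda z: s}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    if polished.fun <= res.fun and abs(s @ polished.x) < 1e-9:
        res = polished
    assert abs(s @ res.x) < 1e-9
    z = np.clip(res.x, 0.0, C)
    beta = z[:n] - z[n:]
    # bias from KKT: free variables pin it; else midpoint of feasible interval
    G = Q @ z + p
    minus_sG = -s * G
    # trust-constr leaves tiny interior values near the bounds; only clearly
    # free variables pin the bias, and the median resists stragglers
    free = (z > 1e-4 * C) & (z < C * (1 - 1e-4))
    if free.any():
        bias = float(np.median(minus_sG[free]))
    else:
        up = np.concatenate([z[:n] < C - 1e-12, z[n:] > 1e-12])
        low = np.concatenate([z[:n] > 1e-12, z[n:] < C - 1e-12])
        bias = float((minus_sG[up].max() + minus_sG[low].min()) / 2.0)

    def predict(Xnew):
        return rbf_gram(np.atleast_2d(Xnew), X, gamma) @ beta + bias

    return float(res.fun), beta, bias, predict


def ols_normal_equations(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares via explicit normal equations."""
    D = np.asarray(D, float)
    return np.linalg.solve(D.T @ D, D.T @ np.asarray(y, float))


def bh_stepup_reference(pvalues) -> np.ndarray:
    """Benjamini-Hochberg by the textbook definition, plain loops."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            j = order[later_pos - 1]
            candidates.append(p[j] * m / later_pos)
        q[idx] = min(1.0, min(candidates))
    return np.array(q)


def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher exact p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        # hypergeometric pmf for cell (0,0) = x
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(1.0, total)


def loo_mad_linear_bruteforce(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out MAD of OLS with intercept, by explicit per-fold refits."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n = y.size
    errs = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        D = np.column_stack([np.ones(n - 1), X[keep]])
        beta = ols_normal_equations(D, y[keep])
        pred = float(np.concatenate([[1.0], X[i]]) @ beta)
        errs.append(abs(pred - y[i]))
    return float(np.mean(errs))


def best_subsets_bruteforce(X: np.ndarray, y: np.ndarray, sizes):
    """Independent exhaustive enumeration of per-size minimal LOO MAD (OLS).

    Returns {size: (min_mad, argmin_indices)} plus the total number of
    subsets scored.
    """
    X = np.atleast_2d(np.asarray(X, float))
    p = X.shape[1]
    out = {}
    count = 0
    for k in sizes:
        best, argmin = np.inf, None
        for combo in itertools.combinations(range(p), k):
            count += 1
            m = loo_mad_linear_bruteforce(X[:, combo], y)
            if m < best - 1e-15 or (abs(m - best) <= 1e-15 and combo < argmin):
                best, argmin = m, combo
        out[k] = (best, argmin)
    return out, count
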