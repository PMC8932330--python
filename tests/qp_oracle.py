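"""Independent reference solution of the binary SVM dual QP.

Solves  max Σα − ½ ΣΣ α_i α_j y_i y_j K_ij  s.t. 0 ≤ α ≤ C, Σ α_i y_i = 0
directly with scipy's SLSQP on small (≤ 20-point) problems, entirely apart
from the package's libsvm-backed training path, then reconstructs decision
values f(x) = Σ α_i y_i K(x, x_i) + b with b averaged over margin vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def rbf(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    sq = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.exp(-np.maximum(sq, 0.0) / sigma**2)


def solve_dual(X: np.ndarray, y: np.ndarray, C: float, sigma: float):
    """Return (alpha, bias) of the soft-margin RBF-SVM dual, y in {-1,+1}."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = rbf(X, X, sigma)
    Q = (y[:, None] * y[None, :]) * K

    def neg_obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def neg_obj_grad(a):
        return Q @ a - np.ones(n)

    res = minimize(
        neg_obj,
        x0=np.full(n, min(C, 1.0) / 2),
        jac=neg_obj_grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y,
                      "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    alpha = res.x
    # bias from KKT: y_i = Σ α_j y_j K_ij + b for margin SVs (0 < α < C)
    margin = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    if not margin.any():
        margin = alpha > 1e-6 * C
    b_vals = y[margin] - (alpha * y) @ K[:, margin]
    return alpha, float(np.mean(b_vals))


def decision_values(
    X_train, y_train, alpha: np.ndarray, bias: float, X: np.ndarray,
    sigma: float,
) -> np.ndarray:
    return rbf(np.atleast_2d(X), np.asarray(X_train, float), sigma) @ (
        alpha * np.asarray(y_train, float)
    ) + bias
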