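"""York linear regression with errors in both coordinates.

Minimises sum_i W_i * (y_i - a*x_i - k)^2 with slope-dependent weights
W_i = w_x w_y / (w_x + a^2 w_y) (uncorrelated errors), iterated to
convergence from an OLS initial slope.  The slope is fitted independently
of the intercept, so a constant offset added to y leaves the slope
unchanged; when the x-errors vanish the solution reduces to weighted
ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class YorkFit:
    slope_a: float
    intercept_k: float
    se_slope: float
    se_intercept: float
    n: int
    iterations: int
    converged: bool


def york_fit(x, y, sx, sy, tol: float = 1e-12, max_iter: int = 100) -> YorkFit:
    """Fit ``y = a*x + k`` with standard errors on both coordinates.

    Parameters
    ----------
    x, y : array_like
        Coordinates (equal lengths, n >= 3).
    sx, sy : array_like or float
        Per-point standard errors (> 0); scalars are broadcast.
    tol : float
        Convergence tolerance on the successive slope change.
    max_iter : int
        Maximum number of weight-update iterations; on non-convergence the
        last iterate is returned with ``converged=False``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    sx = np.broadcast_to(np.asarray(sx, dtype=float), x.shape).copy()
    sy = np.broadcast_to(np.asarray(sy, dtype=float), x.shape).copy()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal lengths")
    if n < 3:
        raise ValueError("at least 3 points are required")
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("all standard errors must be positive")
    if np.ptp(x) == 0:
        raise ValueError("zero x-variance: slope undefined")

    wx = 1.0 / sx ** 2
    wy = 1.0 / sy ** 2

    # OLS initial slope
    xm = x - x.mean()
    b = float((xm @ (y - y.mean())) / (xm @ xm))

    converged = False
    iterations = 0
    W = beta = None
    for iterations in range(1, max_iter + 1):
        W = wx * wy / (wx + b * b * wy)
        sw = W.sum()
        xb = (W @ x) / sw
        yb = (W @ y) / sw
        u = x - xb
        v = y - yb
        beta = W * (u / wy + b * v / wx)
        b_new = float((W * beta) @ v / ((W * beta) @ u))
        if abs(b_new - b) < tol:
            b = b_new
            converged = True
            break
        b = b_new
    # final weights at the converged slope
    W = wx * wy / (wx + b * b * wy)
    sw = W.sum()
    xb = (W @ x) / sw
    yb = (W @ y) / sw
    u = x - xb
    v = y - yb
    beta = W * (u / wy + b * v / wx)
    k = yb - b * xb
    x_adj = xb + beta
    x_adj_bar = (W @ x_adj) / sw
    uu = x_adj - x_adj_bar
    var_b = 1.0 / float(W @ (uu * uu))
    var_k = 1.0 / sw + x_adj_bar ** 2 * var_b
    return YorkFit(
        slope_a=b,
        intercept_k=float(k),
        se_slope=float(np.sqrt(var_b)),
        se_intercept=float(np.sqrt(var_k)),
        n=n,
        iterations=iterations,
        converged=converged,
    )
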