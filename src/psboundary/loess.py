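"""Local polynomial regression (LOESS) with pointwise standard errors.

Implements the classic Cleveland smoother: for each evaluation point the
``floor(span * n)`` nearest observations are weighted by the tricube kernel
on distances scaled by the furthest included neighbour, and a weighted
polynomial (degree 2 by default) is fitted by least squares.  Pointwise
standard errors come from the equivalent-kernel rows l(x) of the smoother
matrix, with the residual variance estimated as RSS / (n - 2 tr L + tr LL')
— the same one-delta correction R's ``loess`` uses — so a 95% band is
fit +/- 1.96 se.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LoessFit", "loess"]


@dataclass
class LoessFit:
    x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    residual_sd: float
    span: float
    degree: int

    def band(self, z: float = 1.96) -> tuple[np.ndarray, np.ndarray]:
        return self.fitted - z * self.se, self.fitted + z * self.se


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess(x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2,
          x_eval: np.ndarray | None = None) -> LoessFit:
    """Fit a LOESS curve; evaluate at ``x_eval`` (default: the data points)."""
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be matching 1D arrays")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points")
    q = max(int(math.floor(span * n)), degree + 1)
    q = min(q, n)
    xe = x if x_eval is None else np.asarray(x_eval, dtype=float)

    # smoother rows at the data points, for the variance estimate
    L = np.empty((n, n))
    for i in range(n):
        L[i] = _lrow(x, x[i], q, degree)
    fitted_data = L @ y
    resid = y - fitted_data
    tr_l = np.trace(L)
    tr_llt = float((L * L).sum())
    dof = max(n - 2.0 * tr_l + tr_llt, 1e-8)
    sigma2 = float(resid @ resid) / dof

    fitted = np.empty(xe.size)
    se = np.empty(xe.size)
    for j, x0 in enumerate(xe):
        l = _lrow(x, x0, q, degree)
        fitted[j] = float(l @ y)
        se[j] = math.sqrt(sigma2 * float(l @ l))
    return LoessFit(x=xe, fitted=fitted, se=se, residual_sd=math.sqrt(sigma2),
                    span=span, degree=degree)


def _lrow(x: np.ndarray, x0: float, q: int, degree: int) -> np.ndarray:
    """Equivalent-kernel row: fitted(x0) = l . y."""
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:q]
    dmax = d[idx].max()
    if dmax == 0:
        w = np.zeros_like(x)
        w[idx] = 1.0
    else:
        w = np.zeros_like(x)
        w[idx] = _tricube(d[idx] / dmax)
    active = w > 0
    xa = x[active] - x0
    wa = w[active]
    X = np.vander(xa, degree + 1, increasing=True)
    WX = X * wa[:, None]
    # l_active = e0' (X'WX)^-1 X'W
    xtwx = X.T @ WX
    try:
        beta_row = np.linalg.solve(xtwx, WX.T)[0]
    except np.linalg.LinAlgError:
        beta_row = (np.linalg.pinv(xtwx) @ WX.T)[0]
    l = np.zeros_like(x)
    l[active] = beta_row
    return l
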