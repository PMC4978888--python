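"""Single-kernel linear mixed model fitted by REML.

Model: ``y = F beta + u + eps`` with ``u ~ N(0, K sigma2_g)`` and
``eps ~ N(0, I sigma2_e)`` at the record level; ``K`` is any record-level
covariance kernel (for G-BLUP, ``Z G Z'`` with ``Z`` the record-to-accession
incidence; for a one-way random accession model, ``Z Z'``).

The restricted likelihood is profiled in the variance ratio
``delta = sigma2_e / sigma2_g`` using a one-time eigendecomposition of the
projected kernel ``S K S`` (S the residual-forming matrix of F), then
maximized by a log-grid scan refined with bounded Brent search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import ConvergenceError, ValidationError


@dataclass
class REMLResult:
    delta: float          # sigma2_e / sigma2_g
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray      # GLS fixed-effect estimates
    alpha: np.ndarray     # V^{-1} (y - F beta); BLUP of u is sigma2_g * K alpha
    loglik: float         # restricted log-likelihood at the optimum (up to constant)


def _reml_profile(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """Negative restricted profile log-likelihood in delta (up to constant)."""
    d = xi + delta
    m = xi.size
    return 0.5 * (m * np.log(np.sum(eta2 / d)) + np.sum(np.log(d)))


def reml_fit(
    K: np.ndarray,
    F: np.ndarray,
    y: np.ndarray,
    bounds: tuple[float, float] = (1e-6, 1e6),
    tol: float = 1e-8,
    n_grid: int = 61,
) -> REMLResult:
    """Maximize the restricted likelihood in ``delta`` and return BLUE/BLUP pieces.

    ``bounds`` clamp the variance-ratio search; hitting the upper bound means
    sigma2_g is effectively zero (infinite shrinkage) and is allowed.
    """
    y = np.asarray(y, dtype=float).ravel()
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[0] != y.size:
        F = F.T
    n = y.size
    if K.shape != (n, n):
        raise ValidationError(f"kernel shape {K.shape} does not match {n} records")
    q = np.linalg.matrix_rank(F)
    if n - q < 2:
        raise ValidationError("too few residual degrees of freedom for REML")

    # Eigendecompose S (K + I) S rather than S K S: the +I offset separates
    # the residual space (eigenvalues >= 1) from span(F) (eigenvalues 0), so
    # the kept eigenvectors are genuinely orthogonal to the fixed effects.
    FtF_inv = np.linalg.pinv(F.T @ F)
    KI = K + np.eye(n)
    SK = KI - F @ (FtF_inv @ (F.T @ KI))
    SKS = SK - (SK @ F) @ (FtF_inv @ F.T)
    SKS = (SKS + SKS.T) / 2.0
    vals, U = np.linalg.eigh(SKS)
    order = np.argsort(vals)[::-1][: n - q]
    xi = np.clip(vals[order] - 1.0, 0.0, None)
    eta = U[:, order].T @ y
    eta2 = eta**2

    lo, hi = bounds
    grid = np.geomspace(lo, hi, n_grid)
    vals = [_reml_profile(d, xi, eta2) for d in grid]
    j = int(np.argmin(vals))
    blo = grid[max(j - 1, 0)]
    bhi = grid[min(j + 1, n_grid - 1)]
    if blo == bhi:
        delta = blo
    else:
        res = minimize_scalar(
            _reml_profile,
            args=(xi, eta2),
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": tol},
        )
        if not res.success:
            raise ConvergenceError(
                f"REML bounded search failed: {res.message}; grid trace min at delta={grid[j]:g}"
            )
        delta = float(res.x)
        if _reml_profile(grid[j], xi, eta2) < res.fun:
            delta = float(grid[j])

    sigma2_g = float(np.sum(eta2 / (xi + delta)) / (n - q))
    sigma2_e = float(delta * sigma2_g)

    V = sigma2_g * K + sigma2_e * np.eye(n)
    Vinv_F = np.linalg.solve(V, F)
    Vinv_y = np.linalg.solve(V, y)
    beta = np.linalg.solve(F.T @ Vinv_F, F.T @ Vinv_y)
    alpha = np.linalg.solve(V, y - F @ beta)
    ll = -_reml_profile(delta, xi, eta2)
    return REMLResult(delta, sigma2_g, sigma2_e, beta, alpha, ll)


def blup_with_fixed_ratio(
    K: np.ndarray, F: np.ndarray, y: np.ndarray, delta: float, sigma2_g: float = 1.0
) -> REMLResult:
    """GLS/BLUP pieces at a caller-supplied variance ratio (no REML search)."""
    y = np.asarray(y, dtype=float).ravel()
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[0] != y.size:
        F = F.T
    n = y.size
    V = sigma2_g * (K + delta * np.eye(n))
    Vinv_F = np.linalg.solve(V, F)
    beta = np.linalg.solve(F.T @ Vinv_F, F.T @ np.linalg.solve(V, y))
    alpha = np.linalg.solve(V, y - F @ beta)
    return REMLResult(delta, sigma2_g, delta * sigma2_g, beta, alpha, np.nan)
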