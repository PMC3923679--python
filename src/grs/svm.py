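"""L1-penalized squared-hinge SVM on allele dosages.

The model minimizes

    sum_i max(0, 1 - y_i (beta0 + x_i . beta))^2 + lambda * sum_j |beta_j|

over weights ``beta`` and an unpenalized intercept ``beta0``, with x the raw
(unstandardized) {0,1,2} dosage matrix and y in {-1,+1}. The solver is
cyclic coordinate descent: each coordinate takes a Lipschitz-majorized
second-order step followed by soft-thresholding at lambda, and the intercept
is reset to its exact one-dimensional minimizer after every sweep. Sweeps
over the active (non-zero) set are interleaved with periodic full sweeps;
convergence is declared when a full sweep moves no coordinate by more than
``tol`` relative to the largest weight.

Missing dosages must be imputed (typically to the training-fold SNP mean)
before fitting.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit

from .models import SparseModel

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITERS = 10_000
FULL_SWEEP_EVERY = 10


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} entries")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be coded {-1, +1}")
    if np.isnan(X).any():
        raise ValueError("X contains NaN; impute missing dosages before fitting")
    return X, y


def objective(X: np.ndarray, y: np.ndarray, model: SparseModel) -> float:
    """L1-penalized squared-hinge loss of ``model`` on (X, y)."""
    X, y = _check_xy(X, y)
    beta = np.asarray(model.beta, dtype=np.float64)
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"model has {beta.shape[0]} weights but X has {X.shape[1]} columns"
        )
    margin = 1.0 - y * (model.beta0 + X @ beta)
    hinge = np.maximum(margin, 0.0)
    return float(hinge @ hinge + model.lam * np.abs(beta).sum())


@njit(cache=True, fastmath=True)
def _solve_intercept(y: np.ndarray, f_wo_b0: np.ndarray, beta0: float) -> float:
    """Exact 1-D minimizer of the squared-hinge loss over the intercept.

    The loss is convex piecewise quadratic in beta0; iterating clipped least
    squares on the active margin set reaches the fixed point exactly.
    """
    n = y.shape[0]
    b0 = beta0
    for _ in range(200):
        s = 0.0
        cnt = 0
        for i in range(n):
            if 1.0 - y[i] * (b0 + f_wo_b0[i]) > 0.0:
                s += y[i] - f_wo_b0[i]
                cnt += 1
        if cnt == 0:
            return b0
        b0_new = s / cnt
        # verify the active set is self-consistent (fixed point)
        if abs(b0_new - b0) < 1e-14:
            return b0_new
        b0 = b0_new
    return b0


@njit(cache=True, fastmath=True)
def _update_coord(XT, y, f, beta, lam, col_lip, j, a, c):
    """Exact 1-D minimization of coordinate j; returns the absolute change."""
    n = y.shape[0]
    bj = beta[j]
    half = 0.5 * lam
    if bj == 0.0:
        # fast path: subgradient check at zero in a single fused pass
        s_ac = 0.0
        for i in range(n):
            a[i] = y[i] * XT[j, i]
            c[i] = 1.0 - y[i] * f[i]
            if c[i] > 0.0:
                s_ac += a[i] * c[i]
        if abs(s_ac) <= half:
            return 0.0
    else:
        for i in range(n):
            a[i] = y[i] * XT[j, i]
            c[i] = 1.0 - y[i] * f[i] + a[i] * bj
    # active-set iteration on the piecewise quadratic
    # phi(b) = sum [c - a*b]_+^2 + lam*|b|
    b = bj
    for _ in range(100):
        s_ac = 0.0
        s_aa = 0.0
        for i in range(n):
            if c[i] - a[i] * b > 0.0:
                s_ac += a[i] * c[i]
                s_aa += a[i] * a[i]
        if s_aa == 0.0:
            b_new = 0.0
        elif s_ac > half:
            b_new = (s_ac - half) / s_aa
        elif s_ac < -half:
            b_new = (s_ac + half) / s_aa
        else:
            b_new = 0.0
        if abs(b_new - b) <= 1e-15 * (1.0 + abs(b)):
            b = b_new
            break
        b = b_new
    # descent safeguard: fall back to the Lipschitz-majorized gradient step
    # if the active-set fixed point did not descend
    phi_old = lam * abs(bj)
    phi_new = lam * abs(b)
    g = 0.0
    for i in range(n):
        m_old = c[i] - a[i] * bj
        if m_old > 0.0:
            phi_old += m_old * m_old
            g -= 2.0 * a[i] * m_old
        m_new = c[i] - a[i] * b
        if m_new > 0.0:
            phi_new += m_new * m_new
    if phi_new > phi_old + 1e-12 * (1.0 + phi_old):
        z = bj - g / col_lip[j]
        thr = lam / col_lip[j]
        if z > thr:
            b = z - thr
        elif z < -thr:
            b = z + thr
        else:
            b = 0.0
    d = b - bj
    if d != 0.0:
        beta[j] = b
        for i in range(n):
            f[i] += XT[j, i] * d
    return abs(d)


@njit(cache=True, fastmath=True)
def _cd_fit(
    XT: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta: np.ndarray,
    beta0: float,
    col_lip: np.ndarray,
    tol: float,
    max_iters: int,
    full_every: int,
):
    """Coordinate descent kernel on the transposed (variant-major) matrix.

    Mutates ``beta``; returns (beta0, n_iters, converged, objective_path).
    """
    p, n = XT.shape
    f = np.empty(n)
    for i in range(n):
        acc = beta0
        for j in range(p):
            if beta[j] != 0.0:
                acc += XT[j, i] * beta[j]
        f[i] = acc

    a = np.empty(n)
    c = np.empty(n)
    obj_path = np.empty(max_iters)
    it = 0
    converged = False
    while it < max_iters:
        full = (it % full_every == 0)
        max_change = 0.0
        max_abs_beta = 1e-12
        for j in range(p):
            if col_lip[j] <= 0.0:
                continue
            if not (full or beta[j] != 0.0):
                continue
            d = _update_coord(XT, y, f, beta, lam, col_lip, j, a, c)
            if d > max_change:
                max_change = d
            ab = abs(beta[j])
            if ab > max_abs_beta:
                max_abs_beta = ab

        # intercept: exact 1-D minimizer
        b0_new = _solve_intercept(y, f - beta0, beta0)
        if b0_new != beta0:
            d0 = b0_new - beta0
            beta0 = b0_new
            for i in range(n):
                f[i] += d0
            if abs(d0) > max_change:
                max_change = abs(d0)

        # objective after this sweep
        loss = 0.0
        for i in range(n):
            m = 1.0 - y[i] * f[i]
            if m > 0.0:
                loss += m * m
        l1 = 0.0
        for j in range(p):
            l1 += abs(beta[j])
        obj_path[it] = loss + lam * l1
        it += 1

        if full and max_change / max(max_abs_beta, 1.0) < tol:
            converged = True
            break
    return beta0, it, converged, obj_path[:it]


def _consolidate_duplicates(XT: np.ndarray, beta: np.ndarray) -> None:
    """Merge weights of exactly duplicated columns onto the first index.

    The L1 optimum splits weight arbitrarily across identical columns; the
    documented tie-break is that the first SNP in cyclic order carries the
    whole weight. Merging never increases the objective (margins are
    unchanged and the L1 norm can only shrink).
    """
    nz = np.flatnonzero(beta)
    if nz.size < 2:
        return
    groups: dict[bytes, int] = {}
    for j in nz:
        key = XT[j].tobytes()
        if key in groups:
            first = groups[key]
            beta[first] += beta[j]
            beta[j] = 0.0
        else:
            groups[key] = j


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest L1 penalty at which the all-zero weight vector is optimal.

    With beta = 0 and the intercept at its unconstrained optimum b0, this is
    max_j |d(data loss)/d beta_j| = max_j |-2 sum_i y_i x_ij max(0, 1 - y_i b0)|.
    """
    X, y = _check_xy(X, y)
    if np.all(y == y[0]):
        raise ValueError("labels are constant; nothing to fit")
    b0 = _solve_intercept(y, np.zeros_like(y), 0.0)
    hinge = np.maximum(1.0 - y * b0, 0.0)
    grad = -2.0 * (X.T @ (y * hinge))
    return float(np.abs(grad).max())


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    warm_start: SparseModel | None = None,
    tol: float = DEFAULT_TOL,
    max_iters: int = DEFAULT_MAX_ITERS,
) -> SparseModel:
    """Fit the penalized SVM at a single penalty ``lam``."""
    X, y = _check_xy(X, y)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    n, p = X.shape
    if warm_start is not None:
        beta = np.array(warm_start.beta, dtype=np.float64, copy=True)
        beta0 = float(warm_start.beta0)
        if beta.shape[0] != p:
            raise ValueError("warm start dimension mismatch")
    else:
        beta = np.zeros(p)
        # start the intercept at its intercept-only optimum so that the
        # first sweep sees the correct subgradients (lambda >= lambda_max
        # must return the exactly empty model)
        beta0 = float(_solve_intercept(y, np.zeros_like(y), 0.0))
    XT = np.ascontiguousarray(X.T)  # variant-major for cache-friendly column access
    col_lip = 2.0 * np.einsum("ij,ij->j", X, X)  # per-coordinate Lipschitz bound
    beta0, n_iters, converged, obj_path = _cd_fit(
        XT, y, float(lam), beta, beta0, col_lip, tol, max_iters, FULL_SWEEP_EVERY
    )
    # snap numerically-zero coefficients (floating-point crumbs from the
    # subgradient boundary) to exact zero
    beta[np.abs(beta) < 1e-12 * max(1.0, np.abs(beta).max(initial=0.0))] = 0.0
    _consolidate_duplicates(XT, beta)
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_iters} sweeps "
            f"(lambda={lam:.4g})",
            stacklevel=2,
        )
    model = SparseModel(
        beta=beta,
        beta0=float(beta0),
        lam=float(lam),
        converged=bool(converged),
        n_iters=int(n_iters),
        objective_path=obj_path,
    )
    model.objective = objective(X, y, model)
    return model


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    grid_size: int = 25,
    min_ratio: float = 0.01,
) -> np.ndarray:
    """Geometric penalty grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(X, y)
    return lmax * np.geomspace(1.0, min_ratio, grid_size)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iters: int = DEFAULT_MAX_ITERS,
) -> list[SparseModel]:
    """Fit along a decreasing penalty grid with warm starts."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a nonempty 1-D sequence")
    if grid.size > 1 and np.any(np.diff(grid) >= 0):
        raise ValueError("penalty grid must be strictly decreasing")
    models: list[SparseModel] = []
    prev: SparseModel | None = None
    for lam in grid:
        m = fit(X, y, lam, warm_start=prev, tol=tol, max_iters=max_iters)
        models.append(m)
        prev = m
    return models


def kkt_violation(X: np.ndarray, y: np.ndarray, model: SparseModel) -> float:
    """Maximum violation of the subgradient optimality conditions.

    For zero coordinates |grad_j| must not exceed lambda; for non-zero ones
    grad_j + lambda*sign(beta_j) must vanish. Returns the largest excess,
    scaled by lambda (or absolute when lambda == 0).
    """
    X, y = _check_xy(X, y)
    beta = model.beta
    hinge = np.maximum(1.0 - y * (model.beta0 + X @ beta), 0.0)
    grad = -2.0 * (X.T @ (y * hinge))
    grad0 = -2.0 * np.sum(y * hinge)
    nz = beta != 0
    viol = abs(grad0)
    if nz.any():
        viol = max(viol, np.abs(grad[nz] + model.lam * np.sign(beta[nz])).max())
    if (~nz).any():
        viol = max(viol, max(0.0, np.abs(grad[~nz]).max() - model.lam))
    return float(viol)
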