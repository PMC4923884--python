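"""Slow, independent reference implementations used only as test oracles.

The sparse precision estimate is recomputed here by monotone proximal
gradient descent (ISTA with backtracking) on the penalized negative
log-likelihood f(theta) = -log det theta + tr(S theta) + rho*||theta||_1
(off-diagonal L1 by default). Backtracking rejects steps that leave the
positive-definite cone or violate the quadratic upper bound, so f
decreases monotonically — i.e. the penalized log-likelihood -f is
non-decreasing over iterations — and iteration stops only when the KKT
stationarity residual of the convex problem is tiny, so the returned
point is the optimum to high accuracy for small problems.
"""

from __future__ import annotations

import numpy as np


def _objective(theta: np.ndarray, s: np.ndarray, rho: float, penalize_diagonal: bool) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    return float(-logdet + np.trace(s @ theta) + rho * _l1(theta, penalize_diagonal))


def _l1(theta: np.ndarray, penalize_diagonal: bool) -> float:
    l1 = np.abs(theta).sum()
    if not penalize_diagonal:
        l1 -= np.abs(np.diag(theta)).sum()
    return float(l1)


def _soft_threshold(x: np.ndarray, t: float, penalize_diagonal: bool) -> np.ndarray:
    out = np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
    if not penalize_diagonal:
        np.fill_diagonal(out, np.diag(x))
    return out


def _is_pd(theta: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(theta)
        return True
    except np.linalg.LinAlgError:
        return False


def kkt_residual(theta: np.ndarray, s: np.ndarray, rho: float, penalize_diagonal: bool) -> float:
    """Max violation of the stationarity condition W = S + rho*Z, Z in d||theta||_1."""
    w = np.linalg.inv(theta)
    p = s.shape[0]
    res = 0.0
    for i in range(p):
        for j in range(p):
            if i == j and not penalize_diagonal:
                res = max(res, abs(w[i, i] - s[i, i]))
            elif abs(theta[i, j]) > 1e-12:
                res = max(res, abs(w[i, j] - s[i, j] - rho * np.sign(theta[i, j])))
            else:
                res = max(res, max(0.0, abs(w[i, j] - s[i, j]) - rho))
    return res


def glasso_reference(
    s: np.ndarray,
    rho: float,
    penalize_diagonal: bool = False,
    kkt_tol: float = 1e-10,
    max_iter: int = 100_000,
    return_trace: bool = False,
):
    """Reference graphical-lasso solution by monotone ISTA.

    Returns theta, or (theta, trace) where trace holds the penalized
    log-likelihood after each accepted step (non-decreasing by
    construction).
    """
    s = np.asarray(s, dtype=float)
    p = s.shape[0]
    theta = np.linalg.inv(s + max(rho, 1e-3) * np.eye(p))
    theta = (theta + theta.T) / 2.0
    f = _objective(theta, s, rho, penalize_diagonal)
    trace = [-f]
    step = 1.0
    for _ in range(max_iter):
        if kkt_residual(theta, s, rho, penalize_diagonal) < kkt_tol:
            break
        grad = s - np.linalg.inv(theta)
        grad = (grad + grad.T) / 2.0
        t = step
        accepted = False
        for _bt in range(80):
            cand = _soft_threshold(theta - t * grad, t * rho, penalize_diagonal)
            cand = (cand + cand.T) / 2.0
            if not _is_pd(cand):
                t *= 0.5
                continue
            diff = cand - theta
            bound = float((grad * diff).sum()) + float((diff * diff).sum()) / (2 * t)
            f_cand = _objective(cand, s, rho, penalize_diagonal)
            smooth_now = f - rho * _l1(theta, penalize_diagonal)
            smooth_cand = f_cand - rho * _l1(cand, penalize_diagonal)
            if smooth_cand <= smooth_now + bound + 1e-14:
                accepted = True
                break
            t *= 0.5
        if not accepted:  # at floating-point resolution
            break
        theta, f = cand, f_cand
        trace.append(-f)
        step = min(t * 2.0, 1.0)
    if return_trace:
        return theta, trace
    return theta
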