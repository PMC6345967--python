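"""Classical regularization-parameter selection: L-curve corner and GCV.

The L-curve plots the residual norm against the penalty norm of the
regularized solution over a log-spaced grid of lambda, in log-log axes.
Its "corner" (point of maximum curvature) is a classical heuristic for the
regularization level — but a corner does not always exist, and several
comparable candidates can appear; both situations are reported rather than
silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .solvers import L2Solver, _as_matrix

__all__ = ["LCurve", "l_curve", "gcv"]

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.logspace(-6, 6, 40)


@dataclass
class LCurve:
    lambdas: np.ndarray
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    corner_lambda: float | None
    corner_method: str
    candidates: np.ndarray = field(default_factory=lambda: np.array([]))
    curvature: np.ndarray | None = None


def _default_solver(lam):
    return L2Solver(lambda2=lam)


def l_curve(M, u, solver_factory=None, lambdas=None,
            ambiguity_ratio: float = 0.9) -> LCurve:
    """Trace the L-curve and locate its maximum-curvature corner.

    ``solver_factory(lam)`` must return an unfitted estimator; default is the
    ridge solver, whose penalty norm is ||f||_2 (for an L1 factory the
    estimator's own penalty norm, ||f||_1, is used).  Curvature is computed
    from cubic-spline derivatives of the smoothed log-log curve; if no
    interior maximum exists, or several local maxima come within
    ``ambiguity_ratio`` of the best, no corner is declared and all
    candidates are reported.
    """
    if solver_factory is None:
        solver_factory = _default_solver
    if lambdas is None:
        lambdas = DEFAULT_GRID
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size < 10:
        raise ValueError("lambda grid must have at least 10 points")
    if np.any(np.diff(lambdas) <= 0):
        raise ValueError("lambda grid must be increasing")
    res, sol, keep = [], [], []
    for lam in lambdas:
        try:
            est = solver_factory(lam).fit(M, u)
        except Exception as exc:  # solver failure: drop the point, log it
            logger.warning("l_curve: solver failed at lambda=%g: %s", lam, exc)
            continue
        r = est.result_()
        penalty = r.penalty_l1 if "L1" in r.method else r.penalty_l2
        if r.residual_norm <= 0 or penalty <= 0:
            continue
        res.append(r.residual_norm)
        sol.append(penalty)
        keep.append(lam)
    lambdas = np.asarray(keep)
    res = np.asarray(res)
    sol = np.asarray(sol)
    t = np.log(lambdas)
    x = np.log(res)
    y = np.log(sol)
    # smooth lightly before differentiating: raw finite differences are
    # noise-dominated on nearly flat stretches
    xs = _smooth(x)
    ys = _smooth(y)
    sx = CubicSpline(t, xs)
    sy = CubicSpline(t, ys)
    tt = np.linspace(t[0], t[-1], 20 * t.size)
    x1, x2 = sx(tt, 1), sx(tt, 2)
    y1, y2 = sy(tt, 1), sy(tt, 2)
    speed2 = x1 * x1 + y1 * y1
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(x1 * y2 - y1 * x2) / np.power(np.maximum(speed2, 1e-300), 1.5)
    interior = slice(tt.size // 20, -max(tt.size // 20, 1))
    k_int = kappa[interior]
    t_int = tt[interior]
    peaks = np.nonzero((k_int[1:-1] > k_int[:-2]) & (k_int[1:-1] >= k_int[2:]))[0] + 1
    corner = None
    candidates = np.array([])
    if peaks.size:
        best = peaks[np.argmax(k_int[peaks])]
        strong = peaks[k_int[peaks] >= ambiguity_ratio * k_int[best]]
        candidates = np.exp(t_int[strong])
        if strong.size == 1:
            corner = float(np.exp(t_int[best]))
    return LCurve(
        lambdas=lambdas,
        residual_norms=res,
        solution_norms=sol,
        corner_lambda=corner,
        corner_method="max_curvature_spline",
        candidates=candidates,
        curvature=np.column_stack([np.exp(tt), kappa]),
    )


def _smooth(v, passes=2):
    out = v.astype(float).copy()
    for _ in range(passes):
        out[1:-1] = 0.25 * out[:-2] + 0.5 * out[1:-1] + 0.25 * out[2:]
    return out


def gcv(M, u, lambdas=None):
    """Generalized cross validation for ridge regularization.

    GCV(lam) = 2m ||(I - H)u||^2 / tr(I - H)^2 with the hat matrix
    H = M (M^T M + lam I)^-1 M^T, evaluated efficiently through the SVD of
    M.  Returns (selected lambda, curve as (lam, score, residual) rows where
    residual is the numerator ||(I - H)u||^2).
    """
    Mm = _as_matrix(M)
    u = np.asarray(u, dtype=float).ravel()
    if lambdas is None:
        lambdas = DEFAULT_GRID
    lambdas = np.asarray(lambdas, dtype=float)
    U, s, _ = np.linalg.svd(Mm, full_matrices=False)
    uu = U.T @ u
    total = float(u @ u)
    rows = Mm.shape[0]
    scores = np.empty(lambdas.size)
    resids = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        shrink = s * s / (s * s + lam)
        # ||(I - H)u||^2 = ||u||^2 - sum (2 - shrink) shrink uu^2
        resid = max(total - float(((2.0 - shrink) * shrink * uu) @ uu), 0.0)
        tr = rows - float(shrink.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            scores[i] = rows * resid / tr**2 if tr > 0 else np.inf
        resids[i] = resid
    k = int(np.argmin(scores))
    return float(lambdas[k]), np.column_stack([lambdas, scores, resids])
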