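"""Penalized traction solvers for the regularized inverse problem

    f_hat = argmin_f  || M f - u ||_2^2  +  lambda1 ||R1 f||_1
                                         +  lambda2 ||R2 f||_2^2 .

Five variants are provided as scikit-learn style estimators (X is the
forward operator or its dense matrix, y the stacked displacement vector):

- :class:`L2Solver` — ridge / Tikhonov, R2 = I, solved exactly by Cholesky.
- :class:`L1Solver` — Lasso, R1 = I, coordinate descent backend.
- :class:`ElasticNetSolver` — combined penalty with the (1 + lambda2)
  de-biasing rescaling of the naive minimizer.
- :class:`ProximalGradientSolver` — PGL / PGEN: R1, R2 are orthonormal
  wavelet transforms of each traction component plane and the problem is
  solved by iterative soft thresholding (ISTA).

Module-level ``solve_*`` functions are thin wrappers returning a
:class:`ReconstructionResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet as _SkElasticNet
from sklearn.linear_model import Lasso as _SkLasso

from .forward import ForwardOperator

__all__ = [
    "ReconstructionResult",
    "L2Solver",
    "L1Solver",
    "ElasticNetSolver",
    "ProximalGradientSolver",
    "solve_l2",
    "solve_l1",
    "solve_en",
    "solve_pg",
]

ZERO_CLIP = 1e-9  # |f| below ZERO_CLIP * max|f| is reported as exactly zero


@dataclass
class ReconstructionResult:
    """Outcome of one penalized reconstruction."""

    traction: np.ndarray
    residual_norm: float
    penalty_l1: float
    penalty_l2: float
    method: str
    lambda1: float
    lambda2: float
    iterations: int = 0
    converged: bool = True
    spec: dict = field(default_factory=dict)


def _as_matrix(X):
    if isinstance(X, ForwardOperator):
        return X.matrix
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D operator matrix or ForwardOperator")
    return X


def _validate(X, y):
    M = _as_matrix(X)
    u = np.asarray(y, dtype=float).ravel()
    if u.size != M.shape[0]:
        raise ValueError(f"displacement length {u.size} != operator rows {M.shape[0]}")
    return M, u


class _BaseTractionSolver(BaseEstimator, RegressorMixin):
    """Common fit/predict surface. Fitted attributes: ``coef_`` (the traction
    vector, alias ``traction_``), ``residual_norm_``, ``n_iter_``,
    ``converged_``."""

    def predict(self, X):
        M = _as_matrix(X)
        return M @ self.coef_

    @property
    def traction_(self):
        return self.coef_

    def _finalize(self, M, u, f, n_iter=0, converged=True):
        self.coef_ = f
        self.residual_norm_ = float(np.linalg.norm(M @ f - u))
        self.n_iter_ = int(n_iter)
        self.converged_ = bool(converged)
        return self

    def result_(self) -> ReconstructionResult:
        f = self.coef_
        return ReconstructionResult(
            traction=f,
            residual_norm=self.residual_norm_,
            penalty_l1=float(np.abs(f).sum()),
            penalty_l2=float(np.linalg.norm(f)),
            method=type(self).__name__,
            lambda1=float(getattr(self, "lambda1", 0.0) or 0.0),
            lambda2=float(getattr(self, "lambda2", 0.0) or 0.0),
            iterations=self.n_iter_,
            converged=self.converged_,
            spec=self.get_params(),
        )


class L2Solver(_BaseTractionSolver):
    """Ridge (Tikhonov) regularization, the exact unique minimizer of
    ||Mf - u||^2 + lambda2 ||f||^2 via the normal equations and Cholesky."""

    def __init__(self, lambda2=1.0):
        self.lambda2 = lambda2

    def fit(self, X, y):
        if not self.lambda2 > 0:
            raise ValueError("lambda2 must be > 0")
        M, u = _validate(X, y)
        n = M.shape[1]
        A = M.T @ M
        A[np.diag_indices(n)] += self.lambda2
        f = cho_solve(cho_factor(A, lower=True), M.T @ u)
        return self._finalize(M, u, f)


class L1Solver(_BaseTractionSolver):
    """Lasso regularization ||Mf - u||^2 + lambda1 ||f||_1 via coordinate
    descent.  Exact zeros are reported as zeros."""

    def __init__(self, lambda1=1.0, tol=1e-8, max_iter=100_000):
        self.lambda1 = lambda1
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if not self.lambda1 > 0:
            raise ValueError("lambda1 must be > 0")
        M, u = _validate(X, y)
        rows = M.shape[0]
        backend = _SkLasso(alpha=self.lambda1 / (2.0 * rows), fit_intercept=False,
                           tol=self.tol, max_iter=self.max_iter)
        backend.fit(M, u)
        f = backend.coef_.copy()
        peak = np.abs(f).max()
        if peak > 0:
            f[np.abs(f) < ZERO_CLIP * peak] = 0.0
        converged = backend.n_iter_ < self.max_iter
        if not converged:
            import warnings

            warnings.warn("L1 solver hit max_iter without reaching tol")
        return self._finalize(M, u, f, n_iter=backend.n_iter_, converged=converged)


class ElasticNetSolver(_BaseTractionSolver):
    """Elastic net: ||Mf - u||^2 + lambda1 ||f||_1 + lambda2 ||f||^2.

    By default the returned traction is the corrected estimate, the naive
    minimizer multiplied by (1 + lambda2) — the standard de-biasing that the
    f -> f/(1 + lambda2) substitution encodes.  Set ``rescale=False`` for
    the naive minimizer.
    """

    def __init__(self, lambda1=1.0, lambda2=1.0, rescale=True, tol=1e-8,
                 max_iter=100_000):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.rescale = rescale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if not (self.lambda1 > 0 and self.lambda2 > 0):
            raise ValueError("elastic net requires lambda1 > 0 and lambda2 > 0")
        M, u = _validate(X, y)
        rows = M.shape[0]
        # map onto sklearn's (1/2N)||y - Xw||^2 + a*l1r*||w||_1
        #                     + (a/2)(1-l1r)*||w||^2
        a_l1 = self.lambda1 / (2.0 * rows)
        a_l2 = self.lambda2 / rows
        alpha = a_l1 + a_l2
        l1_ratio = a_l1 / alpha
        backend = _SkElasticNet(alpha=alpha, l1_ratio=l1_ratio,
                                fit_intercept=False, tol=self.tol,
                                max_iter=self.max_iter)
        backend.fit(M, u)
        f = backend.coef_.copy()
        peak = np.abs(f).max()
        if peak > 0:
            f[np.abs(f) < ZERO_CLIP * peak] = 0.0
        if self.rescale:
            f = (1.0 + self.lambda2) * f
        converged = backend.n_iter_ < self.max_iter
        return self._finalize(M, u, f, n_iter=backend.n_iter_, converged=converged)


class ProximalGradientSolver(_BaseTractionSolver):
    """Proximal gradient (ISTA) with wavelet-domain penalties.

    The traction planes (x and y components on the regular grid) are
    transformed with an orthonormal wavelet basis; the L1 penalty
    lambda1 ||2 W f||_1 and, for the elastic-net variant, the quadratic
    penalty lambda2 ||W f||^2 act on the coefficients.  Each iteration takes
    a gradient step of length 1/L on the data term (L from power iteration
    on M^T M) and then soft-thresholds the coefficients; the quadratic
    penalty becomes a coefficient shrinkage factor.  The approximation (DC)
    coefficients are thresholded like detail coefficients by default.
    """

    def __init__(self, lambda1=1.0, lambda2=0.0, wavelet="db4", level=None,
                 threshold_dc=True, tol=1e-6, max_iter=5000, grid_shape=None):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.wavelet = wavelet
        self.level = level
        self.threshold_dc = threshold_dc
        self.tol = tol
        self.max_iter = max_iter
        self.grid_shape = grid_shape

    @property
    def variant(self) -> str:
        return "PGEN" if self.lambda2 > 0 else "PGL"

    def _shape(self, X, n):
        if isinstance(X, ForwardOperator):
            return X.source_grid.shape
        if self.grid_shape is not None:
            return tuple(self.grid_shape)
        side = int(round(np.sqrt(n / 2)))
        if 2 * side * side != n:
            raise ValueError("cannot infer grid shape; pass grid_shape=(nx, ny)")
        return (side, side)

    def fit(self, X, y):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be >= 0")
        wav = pywt.Wavelet(self.wavelet)
        if not wav.orthogonal:
            raise ValueError(f"wavelet {self.wavelet!r} is not orthonormal")
        M, u = _validate(X, y)
        nx, ny = self._shape(X, M.shape[1])
        if 2 * nx * ny != M.shape[1]:
            raise ValueError("grid shape inconsistent with operator columns")
        L = 2.0 * _power_iteration_sq_norm(M)
        thr = 2.0 * self.lambda1 / L  # the factor 2 of R1 folds into the level
        shrink = 1.0 / (1.0 + 2.0 * self.lambda2 / L)
        level = self.level or pywt.dwtn_max_level((ny, nx), wav)
        f = np.zeros(M.shape[1])
        obj = self._objective(M, u, f, wav, level, nx, ny)
        self.objective_history_ = [obj]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            grad = 2.0 * (M.T @ (M @ f - u))
            z = f - grad / L
            f_new = np.empty_like(f)
            planes = z.reshape(ny * nx, 2)
            out = f_new.reshape(ny * nx, 2)
            for c in (0, 1):
                plane = planes[:, c].reshape(ny, nx)
                coeffs = pywt.wavedec2(plane, wav, mode="periodization", level=level)
                coeffs = self._prox(coeffs, thr, shrink)
                rec = pywt.waverec2(coeffs, wav, mode="periodization")
                out[:, c] = rec[:ny, :nx].ravel()
            new_obj = self._objective(M, u, f_new, wav, level, nx, ny)
            self.objective_history_.append(new_obj)
            rel = abs(obj - new_obj) / max(abs(obj), 1e-30)
            f = f_new
            obj = new_obj
            if rel < self.tol:
                converged = True
                break
        return self._finalize(M, u, f, n_iter=it, converged=converged)

    def _prox(self, coeffs, thr, shrink):
        out = []
        approx = coeffs[0]
        if self.threshold_dc:
            approx = pywt.threshold(approx, thr, mode="soft") * shrink
        out.append(approx)
        for details in coeffs[1:]:
            out.append(tuple(pywt.threshold(d, thr, mode="soft") * shrink
                             for d in details))
        return out

    def _objective(self, M, u, f, wav, level, nx, ny):
        data = float(np.sum((M @ f - u) ** 2))
        pen1 = 0.0
        pen2 = 0.0
        planes = f.reshape(ny * nx, 2)
        for c in (0, 1):
            coeffs = pywt.wavedec2(planes[:, c].reshape(ny, nx), wav,
                                   mode="periodization", level=level)
            flat = np.concatenate([coeffs[0].ravel()]
                                  + [d.ravel() for dets in coeffs[1:] for d in dets])
            pen1 += 2.0 * float(np.abs(flat).sum())
            pen2 += float(np.sum(flat**2))
        return data + self.lambda1 * pen1 + self.lambda2 * pen2


def _power_iteration_sq_norm(M, n_iter=200, tol=1e-12, seed=0):
    """Largest squared singular value of M by power iteration on M^T M."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(M.shape[1])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = M.T @ (M @ v)
        lam_new = float(np.linalg.norm(w))
        if lam_new == 0.0:
            return 0.0
        v = w / lam_new
        if abs(lam_new - lam) <= tol * lam_new:
            break
        lam = lam_new
    return lam_new


def solve_l2(M, u, lambda2) -> ReconstructionResult:
    return L2Solver(lambda2=lambda2).fit(M, u).result_()


def solve_l1(M, u, lambda1, **kw) -> ReconstructionResult:
    return L1Solver(lambda1=lambda1, **kw).fit(M, u).result_()


def solve_en(M, u, lambda1, lambda2, **kw) -> ReconstructionResult:
    return ElasticNetSolver(lambda1=lambda1, lambda2=lambda2, **kw).fit(M, u).result_()


def solve_pg(M, u, lambda1, lambda2=0.0, **kw) -> ReconstructionResult:
    return ProximalGradientSolver(lambda1=lambda1, lambda2=lambda2, **kw).fit(M, u).result_()
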