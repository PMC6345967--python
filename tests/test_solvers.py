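import numpy as np
import pytest
import pywt
from scipy.optimize import minimize

from tfmkit.solvers import (ElasticNetSolver, L1Solver, L2Solver,
                            ProximalGradientSolver, solve_en, solve_l1,
                            solve_l2, solve_pg)


def l1_oracle(M, u, lam):
    """Independent Lasso solver: split f = p - q, smooth bound-constrained."""
    n = M.shape[1]

    def obj(z):
        p, q = z[:n], z[n:]
        f = p - q
        r = M @ f - u
        g = 2 * M.T @ r
        return (float(r @ r + lam * (p.sum() + q.sum())),
                np.concatenate([g + lam, -g + lam]))

    res = minimize(obj, np.zeros(2 * n), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * n),
                   options={"maxiter": 10000, "ftol": 1e-16})
    return res.x[:n] - res.x[n:]


class TestL2:
    def test_identity_closed_form(self, rng):
        u = rng.normal(0, 1, 12)
        r = solve_l2(np.eye(12), u, 0.7)
        assert np.allclose(r.traction, u / 1.7, rtol=1e-12)

    def test_norm_shrinks_monotonically(self, rng):
        M = rng.normal(0, 1, (10, 6))
        u = rng.normal(0, 1, 10)
        norms = [np.linalg.norm(solve_l2(M, u, lam).traction)
                 for lam in (0.1, 1.0, 10.0, 1e3, 1e6)]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-4

    def test_matches_independent_minimizer(self, rng):
        M = rng.normal(0, 1, (6, 4))
        u = rng.normal(0, 1, 6)
        ours = solve_l2(M, u, 1.0).traction

        def obj(f):
            return float(np.sum((M @ f - u) ** 2) + np.sum(f**2))

        res = minimize(obj, np.zeros(4), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14,
                                "maxiter": 20000})
        assert np.allclose(ours, res.x, atol=1e-3)

    def test_invalid_lambda(self, rng):
        with pytest.raises(ValueError):
            solve_l2(np.eye(2), np.ones(2), 0.0)


class TestL1:
    def test_identity_soft_threshold(self, rng):
        u = rng.normal(0, 1, 10)
        r = solve_l1(np.eye(10), u, 0.8)
        expect = np.sign(u) * np.maximum(np.abs(u) - 0.4, 0.0)
        assert np.allclose(r.traction, expect, atol=1e-10)

    def test_zero_above_critical_lambda(self, rng):
        M = rng.normal(0, 1, (8, 5))
        u = rng.normal(0, 1, 8)
        lam_max = 2.0 * np.abs(M.T @ u).max()
        assert np.all(solve_l1(M, u, 1.01 * lam_max).traction == 0.0)

    def test_objective_matches_second_solver(self, rng):
        M = rng.normal(0, 1, (6, 4))
        u = rng.normal(0, 1, 6)
        lam = 0.5
        ours = solve_l1(M, u, lam).traction
        ref = l1_oracle(M, u, lam)

        def obj(f):
            return float(np.sum((M @ f - u) ** 2) + lam * np.abs(f).sum())

        assert abs(obj(ours) - obj(ref)) < 1e-6

    def test_exact_zeros_reported(self, rng):
        M = rng.normal(0, 1, (20, 15))
        u = rng.normal(0, 1, 20)
        f = solve_l1(M, u, 5.0).traction
        assert np.any(f == 0.0)


class TestElasticNet:
    def test_identity_closed_form_naive(self, rng):
        u = rng.normal(0, 1, 10)
        l1, l2 = 0.6, 0.7
        r = solve_en(np.eye(10), u, l1, l2, rescale=False)
        expect = np.sign(u) * np.maximum(np.abs(u) - l1 / 2, 0.0) / (1 + l2)
        assert np.allclose(r.traction, expect, atol=1e-10)

    def test_l1_limit(self, rng):
        M = rng.normal(0, 1, (12, 8))
        u = rng.normal(0, 1, 12)
        en = solve_en(M, u, 0.5, 1e-12, rescale=False).traction
        l1 = solve_l1(M, u, 0.5).traction
        assert np.allclose(en, l1, atol=1e-6)

    def test_l2_limit(self, rng):
        M = rng.normal(0, 1, (12, 8))
        u = rng.normal(0, 1, 12)
        en = solve_en(M, u, 1e-10, 0.5).traction / (1 + 0.5)  # undo rescale
        l2 = solve_l2(M, u, 0.5).traction
        assert np.allclose(en, l2, atol=1e-6)

    def test_rescale_convention_switch(self, rng):
        M = rng.normal(0, 1, (12, 8))
        u = rng.normal(0, 1, 12)
        naive = solve_en(M, u, 0.3, 0.4, rescale=False).traction
        corrected = solve_en(M, u, 0.3, 0.4, rescale=True).traction
        assert np.allclose(corrected, 1.4 * naive, rtol=1e-12)

    def test_requires_both_penalties(self, rng):
        with pytest.raises(ValueError):
            solve_en(np.eye(2), np.ones(2), 1.0, 0.0)


class TestProximalGradient:
    def test_unpenalized_converges_to_least_squares(self, rng):
        M = rng.normal(0, 1, (64, 32))
        u = rng.normal(0, 1, 64)
        r = solve_pg(M, u, 0.0, 0.0, grid_shape=(4, 4), tol=1e-14,
                     max_iter=50000)
        ls, *_ = np.linalg.lstsq(M, u, rcond=None)
        assert np.abs(r.traction - ls).max() < 1e-4

    def test_huge_threshold_kills_everything(self, rng):
        M = rng.normal(0, 1, (64, 32))
        u = rng.normal(0, 1, 64)
        assert np.all(solve_pg(M, u, 1e7, 0.0, grid_shape=(4, 4)).traction == 0.0)

    def test_single_step_is_wavelet_soft_threshold(self, rng):
        """With M = I, one ISTA step from zero soft-thresholds the wavelet
        coefficients of u at lambda1 (threshold 2*lambda1/L with L = 2)."""
        u = rng.normal(0, 1, 32)
        est = ProximalGradientSolver(lambda1=0.3, grid_shape=(4, 4),
                                     max_iter=1).fit(np.eye(32), u)
        z = u.reshape(16, 2)
        expect = np.empty_like(z)
        level = pywt.dwtn_max_level((4, 4), "db4")
        for c in (0, 1):
            cs = pywt.wavedec2(z[:, c].reshape(4, 4), "db4",
                               mode="periodization", level=level)
            cs = ([pywt.threshold(cs[0], 0.3, mode="soft")]
                  + [tuple(pywt.threshold(d, 0.3, mode="soft") for d in det)
                     for det in cs[1:]])
            expect[:, c] = pywt.waverec2(cs, "db4", mode="periodization").ravel()
        assert np.allclose(est.coef_, expect.ravel(), atol=1e-12)

    def test_objective_monotone_nonincreasing(self, rng):
        M = rng.normal(0, 1, (40, 32))
        u = rng.normal(0, 1, 40)
        est = ProximalGradientSolver(lambda1=0.4, lambda2=0.2,
                                     grid_shape=(4, 4), max_iter=150).fit(M, u)
        hist = np.array(est.objective_history_)
        assert np.all(np.diff(hist) <= 1e-9 * np.abs(hist[:-1]))

    def test_nonorthonormal_wavelet_rejected(self, rng):
        est = ProximalGradientSolver(lambda1=0.1, wavelet="bior1.3",
                                     grid_shape=(4, 4))
        with pytest.raises(ValueError):
            est.fit(np.eye(32), rng.normal(0, 1, 32))

    def test_non_lattice_shape_rejected(self, rng):
        est = ProximalGradientSolver(lambda1=0.1, grid_shape=(5, 4))
        with pytest.raises(ValueError):
            est.fit(np.eye(32), rng.normal(0, 1, 32))


class TestHomotopy:
    @pytest.mark.parametrize("factory", [
        lambda lam: L2Solver(lambda2=lam),
        lambda lam: L1Solver(lambda1=lam),
        lambda lam: ElasticNetSolver(lambda1=lam, lambda2=0.5 * lam,
                                     rescale=False),
    ], ids=["L2", "L1", "EN"])
    def test_residual_up_penalty_down_with_lambda(self, factory, rng):
        """The L-curve premise: residual non-decreasing, penalty norm
        non-increasing as the penalty weight grows."""
        M = rng.normal(0, 1, (30, 20))
        f0 = np.zeros(20)
        f0[:4] = 3.0
        u = M @ f0 + rng.normal(0, 0.3, 30)
        res, pen = [], []
        for lam in np.logspace(-3, 3, 9):
            r = factory(lam).fit(M, u).result_()
            res.append(r.residual_norm)
            pen.append(r.penalty_l2)
        assert all(b >= a - 1e-9 for a, b in zip(res, res[1:]))
        assert all(b <= a + 1e-9 for a, b in zip(pen, pen[1:]))


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = ElasticNetSolver(lambda1=0.1, lambda2=0.2)
        est2 = est.set_params(**est.get_params())
        assert est2.get_params()["lambda1"] == 0.1

    def test_predict_after_fit(self, rng):
        M = rng.normal(0, 1, (10, 6))
        u = rng.normal(0, 1, 10)
        est = L2Solver(lambda2=1.0).fit(M, u)
        assert np.allclose(est.predict(M), M @ est.coef_)
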