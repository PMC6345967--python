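import numpy as np
import pytest
from scipy import integrate

from tfmkit.bayes import (AdvancedBayesianL2Solver, BayesianL2Solver,
                          StandardizedProblem, _EvidenceModel,
                          estimate_beta_background, log_evidence, map_traction,
                          standardize)
from tfmkit.solvers import solve_l2


def brute_force_log_evidence(Mt, ut, alpha, beta, half=40.0):
    """Marginal likelihood by direct numerical integration (2 unknowns)."""
    m = Mt.shape[0] // 2
    n = Mt.shape[1] // 2

    def integrand(f1, f2):
        f = np.array([f1, f2])
        r = Mt @ f - ut
        pu = np.exp(-beta / 2 * float(r @ r)) / (2 * np.pi / beta) ** m
        pf = np.exp(-alpha / 2 * float(f @ f)) / (2 * np.pi / alpha) ** n
        return pu * pf

    val, _ = integrate.dblquad(integrand, -half, half, -half, half,
                               epsabs=1e-14, epsrel=1e-10)
    return np.log(val)


class TestStandardize:
    def test_columns_centered_and_unit_spread(self, rng):
        M = rng.normal(3.0, 2.0, (30, 8))
        u = rng.normal(1.0, 1.0, 30)
        prob = standardize(M, u)
        assert np.abs(prob.matrix_std.mean(axis=0)).max() < 1e-12
        assert np.abs(prob.matrix_std.std(axis=0, ddof=1) - 1).max() < 1e-10
        assert abs(prob.u_std.mean()) < 1e-12

    def test_idempotent_on_standardized_input(self, rng):
        M = rng.normal(0, 1, (40, 6))
        prob = standardize(M, rng.normal(0, 1, 40))
        again = standardize(prob.matrix_std, prob.u_std)
        assert np.abs(again.matrix_std - prob.matrix_std).max() < 1e-12

    def test_hand_computed_spreads(self):
        M = np.array([[1.0, 2.0], [3.0, 8.0], [5.0, 2.0]])
        prob = standardize(M, np.array([1.0, 2.0, 3.0]))
        # sample stds with the (rows - 1) denominator, by hand
        assert np.isclose(prob.column_spreads[0], 2.0)
        assert np.isclose(prob.column_spreads[1], np.sqrt(12.0))

    def test_zero_spread_column_reported(self, rng):
        M = rng.normal(0, 1, (10, 3))
        M[:, 1] = 4.0
        with pytest.raises(ValueError, match="1"):
            standardize(M, rng.normal(0, 1, 10))

    def test_destandardize_inverts_scaling(self, rng):
        M = rng.normal(0, 1, (20, 4))
        prob = standardize(M, rng.normal(0, 1, 20))
        f_std = rng.normal(0, 1, 4)
        assert np.allclose(prob.destandardize(f_std) * prob.column_spreads,
                           f_std)


class TestMapTraction:
    def test_equals_ridge_on_standardized_problem(self, rng):
        M = rng.normal(0, 1, (20, 6))
        u = rng.normal(0, 1, 20)
        prob = standardize(M, u)
        alpha, beta = 3.0, 5.0
        ours = map_traction(prob, alpha, beta)
        ridge = solve_l2(prob.matrix_std, prob.u_std, alpha / beta).traction
        assert np.abs(ours - ridge / prob.column_spreads).max() < 1e-10

    def test_only_ratio_matters(self, rng):
        M = rng.normal(0, 1, (20, 6))
        prob = standardize(M, rng.normal(0, 1, 20))
        f1 = map_traction(prob, 2.0, 4.0)
        f2 = map_traction(prob, 20.0, 40.0)
        assert np.allclose(f1, f2, rtol=1e-12)

    def test_infinite_prior_shrinks_to_zero(self, rng):
        M = rng.normal(0, 1, (20, 6))
        prob = standardize(M, rng.normal(0, 1, 20))
        assert np.linalg.norm(map_traction(prob, 1e12, 1.0)) < 1e-8


class TestLogEvidence:
    def test_matches_quadrature_one_node(self, rng):
        """n = 1 (two traction components): exact 2-D marginalization."""
        for seed in (0, 1):
            r = np.random.default_rng(seed)
            Mt = r.standard_normal((6, 2))
            prob = standardize(Mt, r.standard_normal(6))
            le = log_evidence(prob, 0.9, 2.1)
            ref = brute_force_log_evidence(prob.matrix_std, prob.u_std, 0.9, 2.1)
            assert abs(le - ref) < 1e-3 * abs(ref)

    def test_scalar_problem_matches_quadrature(self):
        """Minimal m = n = 1 problem (2x2 matrix)."""
        r = np.random.default_rng(3)
        Mt = r.standard_normal((2, 2)) + 2 * np.eye(2)
        prob = StandardizedProblem(matrix_std=Mt, u_std=np.array([0.3, -0.7]),
                                   column_means=np.zeros(2),
                                   column_spreads=np.ones(2), u_mean=0.0)
        le = log_evidence(prob, 1.3, 0.8)
        ref = brute_force_log_evidence(Mt, prob.u_std, 1.3, 0.8, half=30.0)
        assert abs(le - ref) < 1e-6 * max(1.0, abs(ref))

    def test_cholesky_logdet_equals_dense_determinant(self, rng):
        M = rng.normal(0, 1, (30, 20))
        A = 0.5 * np.eye(20) + 2.0 * M.T @ M / 30
        L = np.linalg.cholesky(A)
        assert np.isclose(2 * np.log(np.diag(L)).sum(),
                          np.linalg.slogdet(A)[1], atol=1e-9)

    def test_zero_operator_reduces_to_noise_likelihood(self):
        ut = np.array([0.4, -0.2, 0.1, 0.3])
        prob = StandardizedProblem(matrix_std=np.zeros((4, 2)), u_std=ut,
                                   column_means=np.zeros(2),
                                   column_spreads=np.ones(2), u_mean=0.0)
        beta = 2.5
        le = log_evidence(prob, 1.7, beta)
        analytic = (-beta / 2 * float(ut @ ut) + 2 * np.log(beta)
                    - 2 * np.log(2 * np.pi))
        assert np.isclose(le, analytic, atol=1e-12)

    def test_fast_path_equals_cholesky_route(self, rng):
        M = rng.normal(0, 1, (24, 10))
        u = rng.normal(0, 1, 24)
        prob = standardize(M, u)
        model = _EvidenceModel(prob)
        for alpha, beta in ((0.1, 3.0), (10.0, 0.2), (1e3, 1e-2)):
            assert np.isclose(model.log_evidence(alpha, beta),
                              log_evidence(prob, alpha, beta), rtol=1e-9)


class TestBetaFromBackground:
    def test_known_sigma_recovery(self, rng):
        v = rng.normal(0.0, 0.05, (10_000, 2))
        beta = estimate_beta_background(v)
        assert abs(beta - 400.0) < 0.05 * 400.0

    def test_constant_offset_removed(self, rng):
        v = rng.normal(0.0, 0.05, (5000, 2)) + np.array([3.0, -1.0])
        beta = estimate_beta_background(v)
        assert abs(beta - 400.0) < 0.1 * 400.0

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            estimate_beta_background(rng.normal(0, 1, (5, 2)))


class TestBL2:
    def test_self_consistent_alpha_recovery(self, rng):
        """Traction drawn from the model prior: alpha is recovered."""
        beta0, alpha0 = 100.0, 4.0
        ratios = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            Mt = r.standard_normal((300, 200))
            f = r.normal(0, 1 / np.sqrt(alpha0), 200)
            u = Mt @ f + r.normal(0, 1 / np.sqrt(beta0), 300)
            est = BayesianL2Solver(beta=beta0).fit(Mt, u)
            ratios.append(est.alpha_ / alpha0)
        assert abs(np.mean(ratios) - 1.0) < 0.25

    def test_requires_beta(self, rng):
        with pytest.raises(ValueError):
            BayesianL2Solver().fit(np.eye(4), np.ones(4))

    def test_scale_invariance_of_map(self, rng):
        """Scaling u and M jointly leaves the MAP traction consistent."""
        M = rng.normal(0, 1, (40, 10))
        f0 = rng.normal(0, 1, 10)
        u = M @ f0 + rng.normal(0, 0.1, 40)
        a = BayesianL2Solver(beta=100.0).fit(M, u)
        c = 10.0
        b = BayesianL2Solver(beta=100.0 / c**2).fit(M * c, u * c)
        # same standardized lambda and same physical traction
        assert np.isclose(a.lambda_, b.lambda_, rtol=1e-2)
        assert np.allclose(a.coef_, b.coef_, rtol=1e-2, atol=1e-8)


class TestABL2:
    def test_toy_grid_scan_agrees_with_fixed_point(self, rng):
        M = rng.normal(0, 1, (20, 16))
        f0 = rng.normal(0, 0.5, 16)
        u = M @ f0 + rng.normal(0, 0.05, 20)
        est = AdvancedBayesianL2Solver().fit(M, u)
        a_fp, b_fp = est.fixed_point()
        assert abs(a_fp - est.alpha_) < 0.01 * est.alpha_
        assert abs(b_fp - est.beta_) < 0.01 * est.beta_

    def test_well_specified_recovery(self):
        """alpha and beta both recovered on a well-conditioned problem."""
        alphas, betas = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            M = r.standard_normal((800, 120))
            f = r.normal(0, 1 / np.sqrt(2.0), 120)
            u = M @ f + r.normal(0, 1 / np.sqrt(400.0), 800)
            est = AdvancedBayesianL2Solver().fit(M, u)
            alphas.append(est.alpha_)
            betas.append(est.beta_)
        assert abs(np.median(alphas) - 2.0) < 0.5
        assert abs(np.median(betas) - 400.0) < 40.0
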