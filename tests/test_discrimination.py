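import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn
from scipy.stats import chi2 as chi2_dist

from labeldyn.discrimination import (
    degrees_of_freedom,
    discrimination_report,
    effective_parameter_count,
    gauss_newton_hessian,
    hessian_analysis,
    q_value,
    residual_jacobian,
    verdict,
)


class TestQValue:
    def test_agrees_with_chi2_survival_function(self):
        for dof in range(1, 51):
            for chi2 in (0.0, 0.5, 3.0, 10.0, 50.0, 120.0, 200.0):
                expected = chi2_dist.sf(chi2, df=dof)
                got = q_value(dof, chi2)
                assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)

    def test_agrees_with_direct_integration(self):
        """Cross-check against numerical quadrature of the gamma integrand."""
        for dof, chi2 in [(4, 3.13), (6, 38.28), (8, 12.52), (3, 7.0)]:
            a, x = dof / 2.0, chi2 / 2.0
            lower, _ = quad(lambda t: np.exp(-t) * t ** (a - 1), 0, x)
            expected = 1.0 - lower / gamma_fn(a)
            assert q_value(dof, chi2) == pytest.approx(expected, rel=1e-8)

    def test_unity_at_zero_chi2(self):
        assert q_value(7, 0.0) == 1.0

    def test_strictly_decreasing_in_chi2(self):
        values = [q_value(6, x) for x in np.linspace(0, 80, 41)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            q_value(0, 1.0)
        with pytest.raises(ValueError):
            q_value(3, -1.0)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "n, p, expected", [(22, 16, 6), (22, 18, 4), (29, 21, 8),
                           (29, 18, 11), (46, 24, 22), (10, 0, 10)]
    )
    def test_arithmetic(self, n, p, expected):
        assert degrees_of_freedom(n, p) == expected

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            degrees_of_freedom(5, 9)


class TestVerdict:
    @pytest.mark.parametrize(
        "q, expected",
        [(0.536, "accept"), (0.129, "accept"), (0.051, "accept"),
         (0.05, "marginal"), (0.01, "marginal"), (0.001, "reject"),
         (9.9e-7, "reject")],
    )
    def test_thresholds(self, q, expected):
        assert verdict(q) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            verdict(1.5)


class TestGaussNewtonHessian:
    def test_linear_model_exact_and_step_independent(self):
        """y = X a is curvature-free: the Hessian is 2 Xᵀ W X exactly."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        sigmas = rng.uniform(0.5, 2.0, 12)

        def predict(a):
            return X @ a

        a0 = rng.normal(size=4)
        for step in (1e-3, 1e-5):
            J = residual_jacobian(predict, a0, rel_step=step)
            H = gauss_newton_hessian(J, sigmas)
            expected = 2.0 * (X.T * (1 / sigmas**2)) @ X
            assert np.allclose(H, expected, rtol=1e-6)

    def test_quadratic_chi2_curvature(self):
        """For y_i = Σ_k c_ik a_k², the GN Hessian at a has a closed form."""
        rng = np.random.default_rng(1)
        C = rng.normal(size=(8, 3))
        sigmas = np.full(8, 0.5)
        a0 = rng.uniform(0.5, 1.5, 3)

        def predict(a):
            return C @ (a**2)

        J = residual_jacobian(predict, a0, rel_step=1e-5)
        expected_J = C * (2 * a0)
        assert np.allclose(J, expected_J, rtol=1e-5)
        H = gauss_newton_hessian(J, sigmas)
        expected_H = 2.0 * (expected_J.T * (1 / sigmas**2)) @ expected_J
        assert np.allclose(H, expected_H, rtol=1e-4)

    def test_ignored_parameter_gives_singular_matrix(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        H = gauss_newton_hessian(X, np.ones(3))
        assert np.all(H[:, 1] == 0.0)
        assert np.all(H[1, :] == 0.0)
        assert np.linalg.matrix_rank(H) == 1

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        J = rng.normal(size=(10, 5))
        H = gauss_newton_hessian(J, rng.uniform(0.1, 1.0, 10))
        w = np.linalg.eigvalsh(H)
        assert np.all(w >= -1e-10)


class TestEffectiveParameterCount:
    def test_full_rank_counts_all(self):
        rng = np.random.default_rng(3)
        J = rng.normal(size=(20, 5))
        H = gauss_newton_hessian(J, np.ones(20))
        p_eff, selected = effective_parameter_count(H)
        assert p_eff == 5
        assert len(selected) == 5

    def test_duplicated_parameter_drops_one(self):
        rng = np.random.default_rng(4)
        J = rng.normal(size=(20, 4))
        J = np.column_stack([J, J[:, 0]])  # fifth column duplicates the first
        H = gauss_newton_hessian(J, np.ones(20))
        p_eff, _ = effective_parameter_count(H)
        assert p_eff == 4

    @pytest.mark.parametrize("rank", [1, 2, 4, 6])
    def test_rank_deficient_psd_matrix_counts_rank(self, rank):
        rng = np.random.default_rng(10 + rank)
        P = 8
        vs = rng.normal(size=(rank, P))
        H = sum(np.outer(v, v) for v in vs)
        p_eff, _ = effective_parameter_count(H)
        assert p_eff == rank

    def test_reorder_invariance(self):
        rng = np.random.default_rng(6)
        J = rng.normal(size=(30, 6))
        H = gauss_newton_hessian(J, np.ones(30))
        perm = rng.permutation(6)
        p1, _ = effective_parameter_count(H)
        p2, _ = effective_parameter_count(H[np.ix_(perm, perm)])
        assert p1 == p2

    def test_never_exceeds_rank(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            r = rng.integers(1, 6)
            vs = rng.normal(size=(r, 7))
            H = sum(np.outer(v, v) for v in vs)
            p_eff, _ = effective_parameter_count(H)
            assert p_eff <= np.linalg.matrix_rank(H, tol=1e-8)


class TestHessianAnalysis:
    def test_covariance_matches_direct_inverse(self):
        rng = np.random.default_rng(8)
        J = rng.normal(size=(25, 4))
        H = gauss_newton_hessian(J, rng.uniform(0.5, 1.5, 25))
        analysis = hessian_analysis(H)
        assert analysis.covariance is not None
        direct = np.linalg.inv(H)
        assert np.allclose(np.diag(analysis.covariance), np.diag(direct),
                           rtol=1e-8)

    def test_singular_matrix_has_no_covariance(self):
        v = np.array([1.0, 2.0, 3.0])
        H = np.outer(v, v)
        analysis = hessian_analysis(H)
        assert analysis.covariance is None
        assert analysis.effective_params == 1


class TestDiscriminationReport:
    def test_single_pool_model_rejected(self):
        rep = discrimination_report(22, 16, 38.28)
        assert rep.dof == 6
        assert rep.q == pytest.approx(9.9e-7, rel=0.05)
        assert rep.verdict == "reject"

    def test_channeling_model_accepted(self):
        rep = discrimination_report(22, 18, 3.13)
        assert rep.dof == 4
        assert rep.q == pytest.approx(0.536, abs=0.001)
        assert rep.verdict == "accept"

    def test_fragment_validation_accepted(self):
        rep = discrimination_report(29, 21, 12.52)
        assert rep.dof == 8
        assert rep.q == pytest.approx(0.129, abs=0.001)
        assert rep.verdict == "accept"
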