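import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sglrr import (
    SgLRRParams,
    build_knn_graph,
    generate_subspace_data,
    soft_threshold,
    solve_sglrr,
    symmetric_svt,
    SubspaceSpec,
)
from sglrr.solver import compute_eta1, update_E, update_J, update_Z

from _oracles import prox_symmetric_nuclear


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,eps,expected",
        [(1.2, 0.5, 0.7), (-0.5, 1.0, 0.0), (-2.0, 0.5, -1.5), (3.0, 0.0, 3.0)],
    )
    def test_scalar_values(self, x, eps, expected):
        assert soft_threshold(x, eps) == pytest.approx(expected)

    def test_negative_eps_raises(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(np.float64, (3, 4), elements=st.floats(-100, 100)),
        st.floats(0, 10),
    )
    def test_shrinkage_properties(self, x, eps):
        y = soft_threshold(x, eps)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)  # never grows magnitude
        assert np.all(y * x >= 0)  # never flips sign
        big = np.abs(x) > eps
        np.testing.assert_allclose(np.abs(y[big]), np.abs(x[big]) - eps, atol=1e-12)
        assert np.all(y[~big] == 0)


class TestSymmetricSvt:
    def test_diagonal_example(self):
        np.testing.assert_allclose(
            symmetric_svt(np.diag([3.0, 0.5]), 1.0), np.diag([2.0, 0.0]), atol=1e-12
        )

    def test_zero_matrix(self):
        np.testing.assert_array_equal(symmetric_svt(np.zeros((3, 3)), 0.5), 0.0)

    def test_asymmetric_input_symmetrized(self):
        Q = np.array([[0.0, 2.0], [0.0, 0.0]])
        np.testing.assert_allclose(
            symmetric_svt(Q, 0.5), [[0.0, 0.5], [0.5, 0.0]], atol=1e-12
        )

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            symmetric_svt(np.ones((2, 3)), 0.1)

    def test_matches_numerical_prox_minimizer(self):
        """Output minimizes eps*||P||_* + 1/2 ||P-Q||_F^2 over symmetric P."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            Q = rng.standard_normal((4, 4)) * rng.uniform(0.5, 3)
            eps = rng.uniform(0.1, 2.0)
            P_impl = prox_symmetric_nuclear(Q, eps)
            assert np.linalg.norm(symmetric_svt(Q, eps) - P_impl) < 1e-4


class TestComputeEta1:
    def test_formula_cases(self):
        X = np.diag([2.0, 1.0])  # spectral norm 2
        assert compute_eta1(X, np.zeros((2, 2)), beta=0.0, mu=1.0) == pytest.approx(5.0)
        L = np.diag([3.0, 0.0])  # spectral norm 3
        assert compute_eta1(np.zeros((2, 2)), L, beta=1.0, mu=0.1) == pytest.approx(6.1)
        assert compute_eta1(np.zeros((2, 2)), L, beta=0.0, mu=0.0) == 0.0


class TestElementwiseUpdates:
    def test_update_E_shrinks_residual(self):
        X = np.array([[1.0, -0.2], [0.05, 3.0]])
        # Z = 0, Y1 = 0 so the argument is X itself; gamma/mu = 0.1
        E = update_E(X, np.zeros((2, 2)), np.zeros((2, 2)), mu=1.0, gamma=0.1)
        np.testing.assert_allclose(E, [[0.9, -0.1], [0.0, 2.9]], atol=1e-12)

    def test_update_E_identity_when_threshold_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((3, 4))
        Z = rng.standard_normal((4, 4))
        Y1 = rng.standard_normal((3, 4))
        E = update_E(X, Z, Y1, mu=2.0, gamma=1e-300)
        np.testing.assert_allclose(E, X - X @ Z + Y1 / 2.0, atol=1e-12)

    def test_update_E_large_threshold_zeroes(self):
        X = np.ones((2, 2))
        E = update_E(X, np.zeros((2, 2)), np.zeros((2, 2)), mu=1.0, gamma=10.0)
        np.testing.assert_array_equal(E, 0.0)

    def test_update_J_nonnegative_shrinkage(self):
        Z = np.array([[0.5, -0.3], [-0.3, 0.2]])
        J = update_J(Z, np.zeros((2, 2)), mu=1.0, lambda_sparse=0.1)
        np.testing.assert_allclose(J, [[0.4, 0.0], [0.0, 0.1]], atol=1e-12)

    def test_update_J_all_negative_gives_zero(self):
        J = update_J(-np.ones((3, 3)), np.zeros((3, 3)), mu=1.0, lambda_sparse=0.1)
        np.testing.assert_array_equal(J, 0.0)

    def test_update_J_identity_on_nonnegative_when_lambda_zero(self):
        Z = np.abs(np.random.default_rng(6).standard_normal((3, 3)))
        np.testing.assert_allclose(
            update_J(Z, np.zeros((3, 3)), mu=1.0, lambda_sparse=0.0), Z, atol=1e-12
        )


class TestUpdateZ:
    def test_zero_state_substitution(self):
        """From a zero start the prox point is (mu/eta1) X^T X."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 5))
        n = 5
        Zk = Jk = Y2 = np.zeros((n, n))
        Ek = Y1 = np.zeros((4, n))
        mu = 0.3
        eta1 = compute_eta1(X, np.zeros((n, n)), beta=0.0, mu=mu)
        Z = update_Z(Zk, Jk, Ek, Y1, Y2, X, np.zeros((n, n)), 0.0, mu, eta1)
        expected = symmetric_svt(mu / eta1 * (X.T @ X), 1.0 / eta1)
        np.testing.assert_allclose(Z, expected, atol=1e-12)

    def test_zero_input_gives_zero(self):
        n = 4
        Z = update_Z(
            np.zeros((n, n)), np.zeros((n, n)), np.zeros((2, n)),
            np.zeros((2, n)), np.zeros((n, n)), np.zeros((2, n)),
            np.zeros((n, n)), 1.0, 0.5, 1.0,
        )
        np.testing.assert_array_equal(Z, 0.0)

    def test_nonpositive_eta1_raises(self):
        n = 3
        with pytest.raises(RuntimeError):
            update_Z(
                np.zeros((n, n)), np.zeros((n, n)), np.zeros((2, n)),
                np.zeros((2, n)), np.zeros((n, n)), np.zeros((2, n)),
                np.zeros((n, n)), 1.0, 0.5, 0.0,
            )

    def test_matches_linearized_subproblem_minimizer(self):
        """One Z step solves min ||Z||_* + <grad, Z-Zk> + eta1/2 ||Z-Zk||_F^2."""
        rng = np.random.default_rng(8)
        m, n = 4, 5
        X = rng.standard_normal((m, n))
        L = np.diag(rng.uniform(0, 2, n))
        Zk = rng.standard_normal((n, n))
        Zk = 0.5 * (Zk + Zk.T)
        Jk = np.abs(rng.standard_normal((n, n)))
        Ek = 0.1 * rng.standard_normal((m, n))
        Y1 = 0.1 * rng.standard_normal((m, n))
        Y2 = 0.1 * rng.standard_normal((n, n))
        beta, mu = 0.5, 0.7
        eta1 = compute_eta1(X, L, beta, mu)
        Z_impl = update_Z(Zk, Jk, Ek, Y1, Y2, X, L, beta, mu, eta1)
        # the linearized subproblem is the prox of the nuclear norm at the
        # gradient-step point: check against the numerical prox oracle
        grad = (
            beta * (Zk @ L.T + Zk @ L)
            + mu * (Zk - Jk + Y2 / mu)
            + mu * (X.T @ (X @ Zk - X + Ek - Y1 / mu))
        )
        Z_oracle = prox_symmetric_nuclear(Zk - grad / eta1, 1.0 / eta1)
        assert np.linalg.norm(Z_impl - Z_oracle) < 1e-4


class TestSgLRRParams:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(gamma=0.0),
            dict(gamma=-1.0),
            dict(rho=1.0),
            dict(mu0=0.0),
            dict(mu0=10.0, mu_max=1.0),
            dict(tol_primal=0.0),
            dict(max_iter=0),
            dict(lambda_sparse=-0.1),
            dict(k_neighbors=0),
        ],
    )
    def test_invalid_params_raise(self, kw):
        with pytest.raises(ValueError):
            SgLRRParams(**kw)


class TestSolveSgLRR:
    def test_zero_matrix_converges_immediately(self):
        X = np.zeros((3, 5))
        g = build_knn_graph(np.random.default_rng(9).standard_normal((3, 5)), 2)
        sol = solve_sglrr(X, g, SgLRRParams())
        assert sol.converged and sol.n_iter == 1
        np.testing.assert_array_equal(sol.Z, 0.0)
        np.testing.assert_array_equal(sol.E, 0.0)

    def test_converged_solution_contracts(self, clean_fixture, clean_solution):
        """Converged run satisfies the primal-residual and symmetry contracts."""
        _, X, _ = clean_fixture
        sol = clean_solution
        assert sol.converged
        params = SgLRRParams()
        primal = np.linalg.norm(X.values - X.values @ sol.Z - sol.E) / np.linalg.norm(
            X.values
        )
        assert primal <= params.tol_primal
        assert np.abs(sol.Z - sol.Z.T).max() <= 10 * params.tol_primal
        assert np.all(sol.J >= 0)

    def test_residual_history_matches_iterations(self, clean_solution):
        assert len(clean_solution.residual_history) == clean_solution.n_iter
        primals = [r[0] for r in clean_solution.residual_history]
        assert primals[-1] <= SgLRRParams().tol_primal

    def test_clean_single_subspace_error_is_small(self):
        """Noise-free self-expressive data needs no error term: E ~ 0."""
        spec = SubspaceSpec(
            n_subspaces=1, subspace_dim=3, ambient_dim=20,
            samples_per_subspace=30, noise_sigma=0.0, seed=2,
        )
        X, _ = generate_subspace_data(spec)
        g = build_knn_graph(X, 5)
        sol = solve_sglrr(X, g, SgLRRParams(gamma=5.0))
        assert np.linalg.norm(sol.E) / np.linalg.norm(X.values) <= 1e-3

    def test_deterministic_reruns_bit_identical(self, clean_fixture):
        _, X, _ = clean_fixture
        g = build_knn_graph(X, 5)
        p = SgLRRParams(max_iter=30)
        s1 = solve_sglrr(X, g, p)
        s2 = solve_sglrr(X, g, p)
        np.testing.assert_array_equal(s1.Z, s2.Z)
        np.testing.assert_array_equal(s1.E, s2.E)

    def test_non_convergence_warns_not_raises(self, clean_fixture, caplog):
        _, X, _ = clean_fixture
        g = build_knn_graph(X, 5)
        with caplog.at_level("WARNING", logger="sglrr.solver"):
            sol = solve_sglrr(X, g, SgLRRParams(max_iter=3))
        assert not sol.converged
        assert any("did not converge" in r.message for r in caplog.records)

    def test_mismatched_graph_raises(self, clean_fixture):
        _, X, _ = clean_fixture
        g = build_knn_graph(np.random.default_rng(0).standard_normal((5, 7)), 2)
        with pytest.raises(ValueError):
            solve_sglrr(X, g, SgLRRParams())

    def test_symmetric_lrr_reduction_separates_subspaces(self):
        """lambda=0, beta=0 reduces to symmetric LRR: within-subspace affinity
        dominates between-subspace affinity on near-noiseless data."""
        from sglrr import build_affinity

        spec = SubspaceSpec(
            n_subspaces=2, subspace_dim=3, ambient_dim=30,
            samples_per_subspace=25, noise_sigma=1e-4, seed=4,
        )
        X, labels = generate_subspace_data(spec)
        g = build_knn_graph(X, 5)
        sol = solve_sglrr(X, g, SgLRRParams(lambda_sparse=0.0, beta=0.0))
        H = build_affinity(sol.Z).H
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert H[same & off_diag].mean() > 5 * H[~same].mean()
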