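"""Random-projection collocation solver: basis, constrained expressions,
residual/Jacobian assembly, iterative least squares, domain decomposition."""

import numpy as np
import pytest

from grayode import make_graybox_spec, pk, simulate_forward, subsample
from grayode.xtfc import (XTFCBasis, XTFCConfig, SubdomainProblem, build_basis,
                          constrained_expression, iterate_least_squares,
                          solve_decomposed, solve_subdomain)

from conftest import pk_closed_form

CFG = XTFCConfig(N=20, L=30, t_step=10.0, seed=0)


class TestBasis:
    def test_deterministic_given_seed(self):
        t = np.linspace(0, 10, 20)
        a = build_basis(t, CFG)
        b = build_basis(t, CFG)
        assert np.array_equal(a.w, b.w) and np.array_equal(a.b, b.b)

    def test_zero_weights_degenerate_shape(self):
        basis = XTFCBasis(w=np.zeros(5), b=np.zeros(5), t0=0.0, tf=1.0)
        t = np.linspace(0, 1, 7)
        assert np.all(basis.value(t) == 0.0)  # tanh(0) = 0
        d = basis.deriv(t)
        assert np.allclose(d, d[0])  # rows constant

    def test_mapping_coefficient_is_linear_slope(self):
        basis = XTFCBasis(w=np.ones(3), b=np.zeros(3), t0=2.0, tf=12.0,
                          z0=0.0, zf=1.0)
        assert basis.c == pytest.approx(0.1)
        assert np.allclose(basis._z(np.array([2.0, 12.0])), [0.0, 1.0])

    def test_single_point_grid_rejected(self):
        with pytest.raises(ValueError):
            build_basis(np.array([1.0]), CFG)


class TestConstrainedExpression:
    def test_ic_exact_for_random_betas(self):
        rng = np.random.default_rng(1)
        basis = build_basis(np.linspace(0, 10, 20), CFG)
        for _ in range(100):
            beta = rng.normal(0, 10, basis.L)
            u, _ = constrained_expression(basis, beta, ic=3.7, t=np.array([0.0]))
            assert u[0] == 3.7  # exact, not approximate

    def test_zero_beta_constant(self):
        basis = build_basis(np.linspace(0, 10, 20), CFG)
        u, du = constrained_expression(basis, np.zeros(basis.L), 1.5,
                                       np.linspace(0, 10, 9))
        assert np.all(u == 1.5) and np.all(du == 0.0)

    def test_analytic_derivative_matches_finite_difference(self):
        rng = np.random.default_rng(2)
        basis = build_basis(np.linspace(0, 10, 20), CFG)
        beta = rng.normal(0, 1, basis.L)
        t = np.linspace(0.5, 9.5, 50)
        h = 1e-6
        _, du = constrained_expression(basis, beta, 0.0, t)
        up, _ = constrained_expression(basis, beta, 0.0, t + h)
        um, _ = constrained_expression(basis, beta, 0.0, t - h)
        assert np.max(np.abs(du - (up - um) / (2 * h))) < 1e-6

    def test_length_mismatch_rejected(self):
        basis = build_basis(np.linspace(0, 10, 20), CFG)
        with pytest.raises(ValueError):
            constrained_expression(basis, np.zeros(basis.L + 1), 0.0, [0.0])


class TestResidualsAndJacobian:
    @pytest.fixture(scope="class")
    def pk_problem(self, pk_model):
        obs = subsample(simulate_forward(pk_model, t_grid=np.linspace(0, 50, 20)), 20)
        gray = make_graybox_spec(pk_model, ["h"])
        cfg = XTFCConfig(N=15, L=25, t_step=50.0, seed=0)
        t_coll = np.linspace(0, 50, 15)
        basis = build_basis(t_coll, cfg)
        return SubdomainProblem(gray, basis, pk_model.initial_conditions,
                                t_coll, obs)

    def test_jacobian_matches_finite_differences(self, pk_problem):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.5, pk_problem.n_unknowns)
        J = pk_problem.jacobian(x)
        h = 1e-7
        for j in rng.choice(pk_problem.n_unknowns, size=20, replace=False):
            e = np.zeros(pk_problem.n_unknowns)
            e[j] = h
            fd = (pk_problem.residuals(x + e) - pk_problem.residuals(x - e)) / (2 * h)
            assert np.max(np.abs(J[:, j] - fd)) < 1e-6

    def test_pk_residuals_affine(self, pk_problem):
        """The gray-box PK system is linear: J is independent of the point."""
        rng = np.random.default_rng(4)
        J1 = pk_problem.jacobian(rng.normal(0, 1, pk_problem.n_unknowns))
        J2 = pk_problem.jacobian(rng.normal(0, 1, pk_problem.n_unknowns))
        assert np.allclose(J1, J2)

    def test_decoupling_block_structure(self, pk_problem):
        """The G equation involves only its own weights (no B coupling), and
        the gray-box B equation involves only the B and h weights."""
        x = np.zeros(pk_problem.n_unknowns)
        J = pk_problem.jacobian(x)
        N, L = 15, 25
        rows_G = slice(N, 2 * N)
        assert np.all(J[rows_G, 0:L] == 0.0)          # dL_G/dbeta_B = 0
        rows_B = slice(0, N)
        assert np.all(J[rows_B, L:2 * L] == 0.0)      # dL_B/dbeta_G = 0

    def test_data_block_is_basis_difference(self, pk_problem):
        x = np.zeros(pk_problem.n_unknowns)
        J = pk_problem.jacobian(x)
        N, L, M = 15, 25, pk_problem.t_data.size
        block = J[3 * N:3 * N + M, 0:L] / pk_problem.row_weights[3 * N:3 * N + M, None]
        assert np.allclose(block, pk_problem.Sd0)

    def test_exact_solution_zeroes_residuals(self, pk_problem):
        """Output weights fitted to the closed-form trajectory and true h
        give a near-zero stacked residual."""
        t = pk_problem.t_colloc
        B, G, U = pk_closed_form(t)
        Y = np.column_stack([B, G, U])
        dY = np.column_stack([0.72 * G - 0.15 * B, -0.72 * G, 0.15 * B])
        # fit values and derivatives jointly so the interpolant's slope is right
        A = np.vstack([pk_problem.Sc0, pk_problem.dSc])
        betas = np.linalg.lstsq(A, np.vstack([Y - pk_problem.ic, dY]), rcond=None)[0].T
        h_t = 0.72 * G - 0.15 * B
        bh = np.linalg.lstsq(pk_problem.Sc, h_t, rcond=None)[0]
        x = np.concatenate([betas.ravel(), bh])
        assert np.linalg.norm(pk_problem.residuals(x)) < 1e-3


class TestIterateLeastSquares:
    def test_affine_system_converges_in_one_iteration(self):
        rng = np.random.default_rng(5)
        A = rng.normal(0, 1, (30, 10))
        b = rng.normal(0, 1, 30)
        x, n_iter = iterate_least_squares(lambda x: A @ x - b, lambda x: A,
                                          np.zeros(10), CFG)
        assert n_iter == 1
        assert np.allclose(x, np.linalg.lstsq(A, b, rcond=None)[0], atol=1e-9)

    def test_square_system_step_is_exact_solve(self):
        rng = np.random.default_rng(6)
        A = rng.normal(0, 1, (5, 5)) + 3 * np.eye(5)
        b = rng.normal(0, 1, 5)
        x, _ = iterate_least_squares(lambda x: A @ x - b, lambda x: A,
                                     np.zeros(5), CFG)
        assert np.allclose(x, np.linalg.solve(A, b), atol=1e-9)

    def test_rank_deficient_returns_minimum_norm(self):
        # duplicated column: solutions of x1 + x2 = 2 form a line; the
        # minimum-norm solution is (1, 1)
        A = np.array([[1.0, 1.0], [2.0, 2.0]])
        b = np.array([2.0, 4.0])
        x, _ = iterate_least_squares(lambda x: A @ x - b, lambda x: A,
                                     np.zeros(2), CFG)
        assert np.allclose(x, [1.0, 1.0], atol=1e-9)

    def test_non_finite_residual_raises(self):
        def residual(x):
            return np.array([np.inf])

        with pytest.raises(RuntimeError):
            iterate_least_squares(residual, lambda x: np.array([[1.0]]),
                                  np.array([1.0]),
                                  XTFCConfig(N=5, L=5, t_step=1.0, max_iter=60))

    def test_uphill_only_direction_stops_without_moving_far(self):
        # every step along the GN direction increases the residual: the
        # iteration must stop gracefully rather than accept garbage
        def residual(x):
            return np.array([np.exp(min(x[0], 500)) + 1.0])

        def jac(x):
            return np.array([[-np.exp(min(x[0], 500))]])

        x, n_iter = iterate_least_squares(residual, jac, np.array([1.0]),
                                          XTFCConfig(N=5, L=5, t_step=1.0,
                                                     max_iter=60))
        assert np.isfinite(residual(x)[0])


class TestSolves:
    def test_pk_forward_matches_closed_form(self, pk_model):
        t = np.linspace(0, 50, 201)
        traj = simulate_forward(pk_model, t_grid=t, method="xtfc-forward")
        B, G, U = pk_closed_form(t)
        assert np.max(np.abs(traj["G"] - G)) < 1e-8
        assert np.max(np.abs(traj["B"] - B)) < 1e-8

    def test_parameter_recovery_under_one_percent(self, pk_model):
        """Noiseless PK data, M >= 50: both rates recovered to < 1 %."""
        obs = subsample(simulate_forward(pk_model, t_grid=np.linspace(0, 50, 50)), 50)
        for seed in range(10):
            cfg = XTFCConfig(N=100, L=100, t_step=50.0, seed=seed,
                             weight_range=(-2, 2))
            rec = solve_decomposed(pk_model, obs, cfg, mode="params")
            assert abs(rec.params["kg"] - 0.72) / 0.72 < 0.01
            assert abs(rec.params["kb"] - 0.15) / 0.15 < 0.01

    def test_interface_continuity(self, pk_model):
        """State value at a subdomain end equals the next subdomain's start."""
        obs = subsample(simulate_forward(pk_model, t_grid=np.linspace(0, 50, 40)), 40)
        gray = make_graybox_spec(pk_model, ["h"])
        cfg = XTFCConfig(N=13, L=40, t_step=12.5, seed=0)
        rec = solve_decomposed(gray, obs, cfg, mode="graybox",
                               t_eval=np.array([12.5 - 1e-9, 12.5]))
        vals = rec.trajectory[["B", "G", "U"]].to_numpy()
        assert np.max(np.abs(vals[1] - vals[0])) < 1e-6

    def test_expected_subdomain_count(self, pk_model, pk_obs_100):
        gray = make_graybox_spec(pk_model, ["h"])
        cfg = XTFCConfig(N=26, L=100, t_step=12.5, seed=0)
        rec = solve_decomposed(gray, pk_obs_100, cfg, mode="graybox")
        assert len(rec.iterations) == 4  # 50 / 12.5

    def test_graybox_closure_consistency(self, pk_model, pk_obs_100):
        """Integrating dB/dt = recovered h(t) reproduces the B data."""
        from scipy.integrate import cumulative_trapezoid
        gray = make_graybox_spec(pk_model, ["h"])
        cfg = XTFCConfig(N=26, L=100, t_step=12.5, seed=0, weight_range=(-2, 2))
        rec = solve_decomposed(gray, pk_obs_100, cfg, mode="graybox")
        t = rec.times
        B_rec = cumulative_trapezoid(rec.terms["h"], t, initial=0.0)
        B_true, _, _ = pk_closed_form(t)
        re = np.sqrt(np.sum((B_rec - B_true) ** 2) / np.sum(B_true ** 2))
        assert re < 1e-3

    def test_mode_validation(self, pk_model):
        with pytest.raises(ValueError):
            solve_subdomain(pk_model, None, CFG, pk_model.initial_conditions,
                            mode="nonsense")
        with pytest.raises(ValueError):
            solve_subdomain(pk_model, None, CFG, pk_model.initial_conditions,
                            mode="params")  # parameter discovery needs data
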