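"""Unit tests for the l1 LRMD solver and its l2 / NMF baselines."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import assert_monotone_errors
from phenofactor import (ConvergenceDiag, DegenerateInputError, FactorPair,
                         check_convergence, lp_residual, lrmd_decompose,
                         lrmd_rank_one, nmf_decompose, select_initial_factor,
                         solve_lad_coefficient, solve_lad_matrix,
                         svd_truncate, weighted_median)


def l1(X):
    return float(np.abs(X).sum())


# ---------------------------------------------------------------------------
# FactorPair


class TestFactorPair:
    def test_from_raw_normalizes_and_reconstructs(self):
        u, v = np.array([2.0, 1.0, 1.0]), np.array([1.0, 2.0, 1.0, 1.0])
        pair = FactorPair.from_raw([u], [v], p=1)
        assert pair.k == 1
        assert np.isclose(np.abs(pair.u[:, 0]).sum(), 1.0)
        assert np.isclose(np.abs(pair.v[:, 0]).sum(), 1.0)
        assert np.allclose(pair.reconstruction(), np.outer(u, v))

    def test_sign_convention_flips_both_vectors(self):
        pair = FactorPair.from_raw([[-1.0, -1.0]], [[1.0, 2.0]], p=1)
        assert pair.u[:, 0].sum() >= 0
        assert np.allclose(pair.reconstruction(),
                           np.outer([-1.0, -1.0], [1.0, 2.0]))

    def test_zero_component_dropped(self):
        pair = FactorPair.from_raw([[1.0, 1.0], [0.0, 0.0]],
                                   [[1.0, 2.0], [3.0, 4.0]], p=1)
        assert pair.k == 1

    def test_all_zero_components_rejected(self):
        with pytest.raises(DegenerateInputError):
            FactorPair.from_raw([[0.0, 0.0]], [[0.0, 0.0]], p=1)

    def test_non_unit_norm_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            FactorPair(np.array([2.0, 0.0]), np.array([1.0, 0.0]),
                       np.array([1.0]), p=1)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            FactorPair(np.array([1.0, 0.0]), np.array([1.0, 0.0]),
                       np.array([-1.0]), p=1)

    def test_sign_violation_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            FactorPair(np.array([-0.5, -0.5]), np.array([1.0, 0.0]),
                       np.array([1.0]), p=1)

    def test_rank_exceeding_min_dim_rejected(self):
        u = np.column_stack([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="rank"):
            FactorPair(u, u, np.ones(3), p=1)


# ---------------------------------------------------------------------------
# lp_residual / check_convergence


class TestLpResidual:
    def test_exact_rank_one_is_zero(self):
        X = np.outer([1.0, 1.0], [1.0, 2.0])
        pair = FactorPair.from_raw([[1.0, 1.0]], [[1.0, 2.0]], p=1)
        assert lp_residual(X, pair, p=1) == pytest.approx(0.0, abs=1e-12)

    def test_identity_with_unit_factor_leaves_one(self):
        pair = FactorPair(np.array([1.0, 0.0]), np.array([1.0, 0.0]),
                          np.array([1.0]), p=1)
        assert lp_residual(np.eye(2), pair, p=1) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(4, 3))
        pair = FactorPair.from_raw([rng.normal(size=4)], [rng.normal(size=3)],
                                   p=1)
        R = pair.reconstruction()
        oracle1 = sum(abs(X[m, n] - R[m, n])
                      for m in range(4) for n in range(3))
        oracle2 = np.sqrt(sum((X[m, n] - R[m, n]) ** 2
                              for m in range(4) for n in range(3)))
        assert lp_residual(X, pair, p=1) == pytest.approx(oracle1, abs=1e-12)
        assert lp_residual(X, pair, p=2) == pytest.approx(oracle2, abs=1e-12)

    def test_shape_mismatch_raises(self):
        pair = FactorPair.from_raw([[1.0, 1.0]], [[1.0, 2.0]], p=1)
        with pytest.raises(ValueError, match="conform"):
            lp_residual(np.eye(3), pair, p=1)


class TestCheckConvergence:
    def test_identical_matrices(self):
        X = np.ones((2, 2))
        assert check_convergence(X, X, 1e-7) is True

    def test_small_but_visible_difference(self):
        X = np.ones((2, 2))
        Y = X.copy()
        Y[0, 0] += 1e-3
        assert check_convergence(X, Y, 1e-7) is False

    def test_three_four_five(self):
        X = np.zeros((1, 2))
        Y = np.array([[3.0, 4.0]])
        assert check_convergence(X, Y, 5.1) is True
        assert check_convergence(X, Y, 5.0) is False

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            check_convergence(np.ones((2, 2)), np.ones((2, 3)), 1e-7)


# ---------------------------------------------------------------------------
# initialization


class TestSelectInitialFactor:
    def test_row_norm_wins(self):
        X = np.array([[1.0, -2.0], [3.0, 4.0]])
        vec, orientation, idx = select_initial_factor(X)
        assert orientation == "row" and idx == 1
        assert np.allclose(vec, [3.0, 4.0])

    def test_tie_prefers_column(self):
        X = np.array([[5.0, 0.0], [0.0, 1.0]])
        vec, orientation, idx = select_initial_factor(X)
        assert orientation == "column" and idx == 0
        assert np.allclose(vec, [5.0, 0.0])

    def test_identity_ties_resolve_to_first_column(self):
        vec, orientation, idx = select_initial_factor(np.eye(2))
        assert orientation == "column" and idx == 0
        assert np.allclose(vec, [1.0, 0.0])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            select_initial_factor(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# LAD subproblems


def lad_objective(u, x, v):
    return float(np.abs(np.asarray(x) - v * np.asarray(u)).sum())


class TestSolveLadCoefficient:
    def test_exact_multiple(self):
        v = solve_lad_coefficient([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert v == pytest.approx(2.0)
        assert lad_objective([1, 1, 1], [2, 2, 2], v) == pytest.approx(0.0)

    def test_robust_to_outlier(self):
        assert solve_lad_coefficient([1.0, 1.0, 1.0],
                                     [1.0, 2.0, 100.0]) == pytest.approx(2.0)

    def test_weighted_example(self):
        u, x = [1.0, 2.0], [3.0, 10.0]
        v = solve_lad_coefficient(u, x)
        assert v == pytest.approx(5.0)
        assert lad_objective(u, x, v) == pytest.approx(2.0)
        # spot checks from the derivation: f(3)=4, f(4)=3, f(5)=2
        assert lad_objective(u, x, 3.0) == pytest.approx(4.0)
        assert lad_objective(u, x, 4.0) == pytest.approx(3.0)

    def test_zero_direction_rejected(self):
        with pytest.raises(DegenerateInputError):
            solve_lad_coefficient([0.0, 0.0], [1.0, 2.0])

    def test_interval_optimum_returns_left_endpoint(self):
        # equal weights, even count: any v in [1, 2] is optimal
        assert weighted_median([1.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    def test_breakpoint_oracle(self, seed):
        # the LAD objective is piecewise linear in v with vertices at the
        # ratios x_i/u_i, so the exact optimum is the best breakpoint
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 7))
        u = rng.normal(size=m)
        u[rng.integers(m)] = 1.0  # ensure at least one nonzero entry
        x = rng.normal(size=m) * 3
        v = solve_lad_coefficient(u, x)
        breakpoints = x[u != 0] / u[u != 0]
        best = min(lad_objective(u, x, b) for b in breakpoints)
        assert lad_objective(u, x, v) <= best + 1e-9


class TestSolveLadMatrix:
    def test_exactly_representable_recovers_coefficients(self):
        rng = np.random.default_rng(11)
        U = rng.normal(size=(5, 2))
        C = rng.normal(size=(2, 4))
        V = solve_lad_matrix(U, U @ C)
        assert np.allclose(V, C, atol=1e-7)

    def test_k1_consistency_with_coefficient_solver(self):
        rng = np.random.default_rng(12)
        u = rng.normal(size=6)
        X = rng.normal(size=(6, 5))
        V = solve_lad_matrix(u[:, None], X)
        for j in range(5):
            assert V[0, j] == pytest.approx(
                solve_lad_coefficient(u, X[:, j]))

    def test_k2_grid_search_oracle(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, -1.0]])
        x = np.array([1.0, 2.0, 2.5, 4.0])
        w = solve_lad_matrix(U, x[:, None])[:, 0]
        obj = float(np.abs(x - U @ w).sum())
        grid = np.linspace(-5, 5, 401)
        grid_min = min(float(np.abs(x - U @ np.array([a, b])).sum())
                       for a in grid for b in grid)
        assert obj <= grid_min + 1e-6

    def test_rank_deficient_factor_rejected(self):
        U = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(np.linalg.LinAlgError):
            solve_lad_matrix(U, np.eye(3))


# ---------------------------------------------------------------------------
# LRMD


class TestLrmdRankOne:
    def test_exact_rank_one_input(self):
        X = np.outer([1.0, 1.0], [1.0, 2.0])
        pair, diag = lrmd_rank_one(X)
        assert lp_residual(X, pair, p=1) < 1e-8
        assert diag.converged
        assert_monotone_errors(diag.error_sequence)

    def test_l1_objective_dominates_planted_and_svd_under_outlier(self):
        # planted rank-one plus one gross corruption: the l1-optimal fit
        # must be at least as good as the planted factors (residual 50)
        # and as the l2-optimal rank-one on the same instance
        X = np.outer([2.0, 1.0, 1.0], [1.0, 2.0, 1.0, 1.0])
        X[0, 0] += 50.0
        pair, _ = lrmd_rank_one(X)
        obj_lrmd = lp_residual(X, pair, p=1)
        obj_planted = 50.0
        svd_pair, _ = svd_truncate(X, 1)
        obj_svd = lp_residual(X, svd_pair, p=1)
        assert obj_lrmd <= obj_planted + 1e-9
        assert obj_lrmd <= obj_svd + 1e-9

    def test_error_sequences_monotone_on_random_instances(self):
        for t in range(5):
            rng = np.random.default_rng(4000 + t)
            X = rng.normal(size=(10, 8)) * 3
            X.flat[rng.choice(X.size, 4, replace=False)] += 50
            pair, diag = lrmd_rank_one(X)
            assert_monotone_errors(diag.error_sequence)
            pair.validate()

    def test_max_iter_exhaustion_warns_not_raises(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 6))
        with pytest.warns(RuntimeWarning, match="max_iter"):
            _, diag = lrmd_rank_one(X, max_iter=1)
        assert not diag.converged

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            lrmd_rank_one(np.zeros((3, 3)))


class TestLrmdDecompose:
    @staticmethod
    def planted(seed, k, shape=(12, 9)):
        rng = np.random.default_rng(seed)
        sig = np.array([100.0, 10.0, 1.0][:k])
        U = rng.uniform(0.5, 1.5, (shape[0], k))
        V = rng.uniform(0.5, 1.5, (shape[1], k))
        return (U * sig) @ V.T

    def test_rank_two_deflate_recovers_exactly(self):
        X = self.planted(21, 2)
        pair, diag = lrmd_decompose(X, 2)
        assert lp_residual(X, pair, p=1) / l1(X) < 1e-6
        assert_monotone_errors(diag.error_sequence)

    def test_full_rank_reconstruction_is_exact(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(3, 3)) + 4 * np.eye(3)
        pair, _ = lrmd_decompose(X, 3)
        assert lp_residual(X, pair, p=1) / l1(X) < 1e-6

    def test_rank_one_objective_beats_svd_truncation(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(4, 3)) * 2
        pair, _ = lrmd_decompose(X, 1)
        svd_pair, _ = svd_truncate(X, 1)
        assert (lp_residual(X, pair, p=1)
                <= lp_residual(X, svd_pair, p=1) + 1e-9)

    def test_joint_strategy_also_recovers(self):
        X = self.planted(24, 2)
        pair, _ = lrmd_decompose(X, 2, strategy="joint")
        assert lp_residual(X, pair, p=1) / l1(X) < 1e-6

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            lrmd_decompose(np.eye(3), 4)
        with pytest.raises(ValueError, match="out of range"):
            lrmd_decompose(np.eye(3), 0)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            lrmd_decompose(np.eye(3), 1, strategy="magic")

    def test_scale_equivariance(self):
        X = self.planted(25, 2)
        c = 3.5
        pair1, _ = lrmd_decompose(X, 2)
        pair2, _ = lrmd_decompose(c * X, 2)
        assert np.allclose(pair2.sigmas, c * pair1.sigmas, rtol=1e-8)
        assert np.allclose(pair2.u, pair1.u, atol=1e-8)
        assert np.allclose(pair2.v, pair1.v, atol=1e-8)

    def test_vanishing_residual_returns_fewer_components(self):
        X = np.outer([1.0, 2.0, 3.0], [1.0, 1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="lower-rank"):
            pair, _ = lrmd_decompose(X, 2)
        assert pair.k == 1
        assert lp_residual(X, pair, p=1) / l1(X) < 1e-10


# ---------------------------------------------------------------------------
# baselines


class TestSvdTruncate:
    def test_exact_rank_one(self):
        X = np.outer([1.0, 2.0], [3.0, 4.0, 5.0])
        pair, recon = svd_truncate(X, 1)
        assert np.allclose(recon, X, atol=1e-10)
        assert pair.p == 2

    def test_diagonal_analytic_case(self):
        pair, recon = svd_truncate(np.diag([3.0, 1.0]), 1)
        assert np.allclose(recon, np.diag([3.0, 0.0]), atol=1e-12)
        assert lp_residual(np.diag([3.0, 1.0]), pair, p=2) == pytest.approx(1.0)

    def test_matches_closed_form_truncation(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(5, 4))
        for k in (1, 2, 3):
            _, recon = svd_truncate(X, k)
            U, s, Vt = np.linalg.svd(X, full_matrices=False)
            closed = (U[:, :k] * s[:k]) @ Vt[:k]
            assert np.allclose(recon, closed, atol=1e-8)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            svd_truncate(np.eye(3), 5)

    def test_rank_deficient_input_drops_zero_components(self):
        X = np.outer([1.0, 2.0, 3.0], [1.0, 1.0, 2.0])
        with pytest.warns(RuntimeWarning, match="rank"):
            pair, _ = svd_truncate(X, 2)
        assert pair.k == 1


class TestNmfDecompose:
    def test_exact_nonnegative_rank_one(self):
        V = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        W, H, trace = nmf_decompose(V, 1, seed=0, max_iter=2000, tol=1e-14)
        assert trace[-1] / np.linalg.norm(V) < 1e-4

    def test_nonnegativity_and_monotone_trace(self):
        rng = np.random.default_rng(33)
        V = rng.random((6, 5))
        W, H, trace = nmf_decompose(V, 2, seed=33)
        assert W.min() >= 0 and H.min() >= 0
        assert np.all(np.diff(trace) <= 1e-12 * max(1.0, trace[0]))

    def test_determinism(self):
        V = np.random.default_rng(34).random((4, 4))
        a = nmf_decompose(V, 2, seed=5)
        b = nmf_decompose(V, 2, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nmf_decompose(np.array([[1.0, -0.1], [0.0, 1.0]]), 1)

    def test_matches_sklearn_objective(self):
        sklearn_nmf = pytest.importorskip("sklearn.decomposition").NMF
        rng = np.random.default_rng(9)
        V = rng.random((6, 5)) * 2
        _, _, trace = nmf_decompose(V, 2, seed=9, max_iter=2000, tol=1e-12)
        sk = sklearn_nmf(n_components=2, init="random", random_state=9,
                         max_iter=2000, tol=1e-10).fit(V)
        err_sk = np.linalg.norm(V - sk.transform(V) @ sk.components_)
        assert trace[-1] == pytest.approx(err_sk, rel=1e-3)


def test_convergence_diag_defaults():
    diag = ConvergenceDiag()
    assert diag.error_sequence == [] and not diag.converged
    assert diag.epsilon == pytest.approx(1e-7)
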