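"""SDP relaxation, LDL factorization, hyperplane rounding, brute-force oracle."""

import numpy as np
import pytest

from maxcomp.maxcut_sdp import (approx_factorize, brute_force_maxcut,
                                cut_objective, round_hyperplane, solve_maxcut,
                                solve_sdp)


def _laplacian(W):
    return np.diag(W.sum(axis=1)) - W


def _random_complete(rng, n):
    W = rng.uniform(0, 1, (n, n))
    W = np.triu(W, 1)
    return W + W.T


class TestSolveSdp:
    def test_single_edge_rank_one_optimum(self):
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        sol = solve_sdp(L)
        assert sol.sdp_objective == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(sol.A, [[1, -1], [-1, 1]], atol=1e-4)

    def test_triangle_relaxation_optimum(self):
        W = np.ones((3, 3)) - np.eye(3)
        sol = solve_sdp(_laplacian(W))
        # unit vectors at 120 degrees: off-diagonal -1/2, objective 9/4
        assert sol.sdp_objective == pytest.approx(2.25, abs=1e-5)
        off = sol.A[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, -0.5, atol=1e-3)

    def test_empty_graph(self):
        sol = solve_sdp(np.zeros((4, 4)))
        assert sol.sdp_objective == pytest.approx(0.0, abs=1e-9)
        assert sol.dual_bound == pytest.approx(0.0, abs=1e-9)

    def test_solution_contract(self, rng):
        W = _random_complete(rng, 12)
        sol = solve_sdp(_laplacian(W))
        assert sol.solver_status
        np.testing.assert_allclose(np.diag(sol.A), 1.0, atol=1e-6)
        np.testing.assert_allclose(sol.A, sol.A.T, atol=1e-12)
        assert np.linalg.eigvalsh(sol.A)[0] >= -1e-6 * len(sol.A)
        assert sol.dual_bound >= sol.sdp_objective - 1e-9

    def test_bound_dominates_brute_force_optimum(self, rng):
        W = _random_complete(rng, 10)
        _, opt = brute_force_maxcut(W)
        sol = solve_sdp(_laplacian(W))
        assert sol.dual_bound >= opt - 1e-6

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            solve_sdp(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestApproxFactorize:
    def test_identity(self):
        np.testing.assert_allclose(approx_factorize(np.eye(3)) @
                                   approx_factorize(np.eye(3)).T, np.eye(3),
                                   atol=1e-12)

    def test_exact_psd_reproduced(self):
        A = np.array([[1.0, -1.0], [-1.0, 1.0]])
        V = approx_factorize(A)
        np.testing.assert_allclose(V @ V.T, A, atol=1e-9)

    def test_clamping_error_bounded_by_perturbation(self, rng):
        # PSD matrix pushed slightly indefinite: error of the clamped
        # factorization stays of the order of the perturbation
        X = rng.normal(size=(6, 6))
        A = X @ X.T
        A /= np.outer(np.sqrt(np.diag(A)), np.sqrt(np.diag(A)))
        eps = 1e-9
        vals, vecs = np.linalg.eigh(A)
        A_pert = (vecs * (vals - vals[0] - eps)) @ vecs.T  # smallest eig -> -eps
        V = approx_factorize(A_pert)
        assert np.linalg.norm(V @ V.T - A_pert) <= 1e-6

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            approx_factorize(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestRounding:
    def test_antipodal_vectors_always_optimal(self):
        V = np.array([[1.0, 0.0], [-1.0, 0.0]])
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        cut = round_hyperplane(V, L, sdp_bound=1.0, max_rounds=50, seed=3)
        assert cut.objective == pytest.approx(1.0)
        assert cut.n_rounds == 1

    def test_triangle_reaches_brute_force_optimum(self):
        W = np.ones((3, 3)) - np.eye(3)
        L = _laplacian(W)
        sol = solve_sdp(L)
        V = approx_factorize(sol.A)
        cut = round_hyperplane(V, L, sdp_bound=None, max_rounds=100, seed=0)
        assert cut.objective == pytest.approx(2.0)  # OPT by enumeration
        assert cut.objective / sol.dual_bound >= 0.878

    def test_seed_determinism(self, rng):
        W = _random_complete(rng, 9)
        L = _laplacian(W)
        sol = solve_sdp(L)
        V = approx_factorize(sol.A)
        a = round_hyperplane(V, L, sdp_bound=sol.dual_bound, seed=42)
        b = round_hyperplane(V, L, sdp_bound=sol.dual_bound, seed=42)
        np.testing.assert_array_equal(a.s, b.s)
        assert a.n_rounds == b.n_rounds and a.objective == b.objective

    def test_max_rounds_exhaustion_returns_best(self):
        V = np.array([[1.0, 0.0], [-1.0, 0.0]])
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        cut = round_hyperplane(V, L, sdp_bound=10.0, max_rounds=5, seed=1)
        assert cut.n_rounds == 5 and cut.objective == pytest.approx(1.0)


class TestCutObjective:
    def test_single_edge_expansion(self):
        W = np.array([[0.0, 0.7], [0.7, 0.0]])
        assert cut_objective(np.array([1, -1]), _laplacian(W)) == pytest.approx(0.7)

    def test_uncut_and_sign_symmetry(self, rng):
        W = _random_complete(rng, 7)
        L = _laplacian(W)
        assert cut_objective(np.ones(7), L) == pytest.approx(0.0, abs=1e-12)
        s = rng.choice([-1, 1], 7)
        assert cut_objective(s, L) == pytest.approx(cut_objective(-s, L))

    def test_rejects_non_pm_one(self):
        with pytest.raises(ValueError):
            cut_objective(np.array([1, 0]), np.zeros((2, 2)))


class TestBruteForce:
    def test_known_small_graphs(self):
        edge = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert brute_force_maxcut(edge)[1] == pytest.approx(1.0)
        triangle = np.ones((3, 3)) - np.eye(3)
        assert brute_force_maxcut(triangle)[1] == pytest.approx(2.0)
        c4 = np.zeros((4, 4))
        for i in range(4):
            c4[i, (i + 1) % 4] = c4[(i + 1) % 4, i] = 1.0
        s, opt = brute_force_maxcut(c4)
        assert opt == pytest.approx(4.0)
        assert np.array_equal(s[::2], -s[1::2])  # alternating cut

    def test_refuses_large_graphs(self):
        with pytest.raises(ValueError):
            brute_force_maxcut(np.zeros((23, 23)))


def test_pipeline_matches_oracle_on_random_graphs(rng):
    """SDP + rounding reaches the exact optimum on most small instances and
    never violates weak duality or the 0.878 guarantee."""
    hits = 0
    for k in range(15):
        W = _random_complete(rng, 8)
        _, opt = brute_force_maxcut(W)
        L = _laplacian(W)
        sol = solve_sdp(L)
        V = approx_factorize(sol.A)
        cut = round_hyperplane(V, L, sdp_bound=None, max_rounds=500, seed=k)
        assert cut.objective <= sol.dual_bound + 1e-6
        assert cut.objective >= 0.878 * opt - 1e-9
        hits += cut.objective >= opt - 1e-9
    assert hits >= 13  # near-universal exact recovery at this size
    # the production path stops early once the guarantee threshold is met
    W = _random_complete(rng, 10)
    cut = solve_maxcut(W, max_rounds=500, seed=5)
    assert cut.objective >= 0.878 * cut.sdp_bound - 1e-9
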