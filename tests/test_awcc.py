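"""Adaptive weighted co-clustering: objective, updates, convergence."""

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st

from hetnetcc import PipelineConfig
from hetnetcc.awcc import (
    CoClusterState,
    fit_awcc,
    objective,
    update_factors,
    update_w,
    view_residuals,
)

from conftest import random_awcc_instance


def objective_loop_oracle(state, W_list, X11, X21, alpha, beta, gamma):
    """Naive elementwise recomputation of the joint objective."""

    def frob2(M):
        total = 0.0
        for row in np.atleast_2d(M):
            for x in row:
                total += x * x
        return total

    G1, G2, B, w = state.G1, state.G2, state.B, state.w
    k = G1.shape[1]
    val = 0.0
    for wi, Wi, Si in zip(w, W_list, state.S_list):
        val += wi * frob2(Wi - G1 @ Si @ G2.T)
    val += alpha * (frob2(X11 - G1 @ B) + frob2(X21 - G2 @ B))
    val += beta * (frob2(G1.T @ G1 - np.eye(k)) + frob2(G2.T @ G2 - np.eye(k)))
    val += gamma * frob2(w)
    return val


def qp_weight_oracle(losses, gamma):
    """Constrained solver for min w.L + gamma ||w||^2 on the simplex."""
    v = len(losses)
    res = scipy.optimize.minimize(
        lambda w: float(w @ losses + gamma * w @ w),
        np.full(v, 1.0 / v),
        jac=lambda w: losses + 2 * gamma * w,
        bounds=[(0, 1)] * v,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    return res.x


def random_state(seed, g, m, n, k, v):
    r = np.random.default_rng(seed)
    w = r.uniform(size=v)
    return CoClusterState(
        G1=r.uniform(size=(g, k)),
        G2=r.uniform(size=(m, k)),
        S_list=[r.uniform(size=(k, k)) for _ in range(v)],
        B=r.uniform(size=(k, n)),
        w=w / w.sum(),
    )


class TestObjective:
    def test_all_zero_factors_leave_only_identity_and_weight_terms(self):
        g, m, n, k, v = 4, 3, 2, 2, 2
        state = CoClusterState(
            G1=np.zeros((g, k)), G2=np.zeros((m, k)),
            S_list=[np.zeros((k, k))] * v, B=np.zeros((k, n)),
            w=np.full(v, 0.5),
        )
        val = objective(state, [np.zeros((g, m))] * v, np.zeros((g, n)),
                        np.zeros((m, n)), alpha=1.0, beta=2.0, gamma=3.0)
        # ||0 - I||_F^2 = k per layer, plus gamma * ||w||^2
        assert val == pytest.approx(2 * 2.0 * 2 + 3.0 * 0.5)

    def test_exact_planted_factorization_leaves_weight_term(self, rng):
        g, m, n, k, v = 6, 4, 5, 2, 2
        # orthonormal non-negative G: disjoint indicator columns, unit norm
        G1 = np.zeros((g, k)); G1[:3, 0] = 1 / np.sqrt(3); G1[3:, 1] = 1 / np.sqrt(3)
        G2 = np.zeros((m, k)); G2[:2, 0] = 1 / np.sqrt(2); G2[2:, 1] = 1 / np.sqrt(2)
        S_list = [rng.uniform(size=(k, k)) for _ in range(v)]
        B = rng.uniform(size=(k, n))
        w = np.array([0.3, 0.7])
        W_list = [G1 @ S @ G2.T for S in S_list]
        state = CoClusterState(G1=G1, G2=G2, S_list=S_list, B=B, w=w)
        val = objective(state, W_list, G1 @ B, G2 @ B, 1.0, 1.0, 2.0)
        assert val == pytest.approx(2.0 * float(w @ w), abs=1e-12)

    def test_matches_loop_oracle_on_random_instance(self):
        W_list, X11, X21 = random_awcc_instance(0, g=6, m=5, n=4, k=2, v=2)
        state = random_state(0, 6, 5, 4, 2, 2)
        fast = objective(state, W_list, X11, X21, 0.7, 1.3, 0.5)
        slow = objective_loop_oracle(state, W_list, X11, X21, 0.7, 1.3, 0.5)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_shape_mismatch_rejected(self):
        W_list, X11, X21 = random_awcc_instance(0)
        state = random_state(0, 8, 6, 5, 2, 2)
        with pytest.raises(ValueError):
            objective(state, W_list, X11[:3], X21, 1, 1, 1)


class TestUpdateFactors:
    def test_single_update_decreases_objective(self):
        W_list, X11, X21 = random_awcc_instance(0)
        state = random_state(0, 8, 6, 5, 2, 2)
        f0 = objective(state, W_list, X11, X21, 1, 1, 1)
        f1 = objective(update_factors(state, W_list, X11, X21, 1, 1, 1),
                       W_list, X11, X21, 1, 1, 1)
        assert f1 < f0

    def test_factors_stay_non_negative_after_many_updates(self):
        W_list, X11, X21 = random_awcc_instance(3)
        state = random_state(3, 8, 6, 5, 2, 2)
        for _ in range(100):
            state = update_factors(state, W_list, X11, X21, 1, 1, 1)
        assert state.G1.min() >= 0 and state.G2.min() >= 0
        assert state.B.min() >= 0 and all(S.min() >= 0 for S in state.S_list)

    def test_near_stationary_at_exact_orthonormal_factorization(self):
        g, m, n, k = 6, 4, 5, 2
        rng = np.random.default_rng(1)
        G1 = np.zeros((g, k)); G1[:3, 0] = 1 / np.sqrt(3); G1[3:, 1] = 1 / np.sqrt(3)
        G2 = np.zeros((m, k)); G2[:2, 0] = 1 / np.sqrt(2); G2[2:, 1] = 1 / np.sqrt(2)
        S_list = [rng.uniform(size=(k, k))]
        B = rng.uniform(size=(k, n))
        w = np.array([1.0])
        W_list = [G1 @ S_list[0] @ G2.T]
        state = CoClusterState(G1=G1, G2=G2, S_list=S_list, B=B, w=w)
        f0 = objective(state, W_list, G1 @ B, G2 @ B, 1, 1, 1)
        f1 = objective(update_factors(state, W_list, G1 @ B, G2 @ B, 1, 1, 1),
                       W_list, G1 @ B, G2 @ B, 1, 1, 1)
        assert abs(f1 - f0) <= 1e-8 * (1 + abs(f0))


class TestUpdateW:
    def test_equal_losses_give_uniform_weights(self):
        np.testing.assert_allclose(update_w(np.full(4, 2.5), gamma=0.7), 0.25)

    def test_huge_gamma_approaches_uniform(self):
        w = update_w(np.array([0.0, 1.0, 2.0]), gamma=1e12)
        np.testing.assert_allclose(w, 1 / 3, atol=1e-6)

    @pytest.mark.parametrize(
        "losses,gamma,expected",
        [([0.0, 1.0], 0.25, [1.0, 0.0]), ([0.0, 1.0], 1.0, [0.75, 0.25])],
    )
    def test_two_view_closed_form(self, losses, gamma, expected):
        np.testing.assert_allclose(update_w(np.array(losses), gamma), expected, atol=1e-12)

    def test_gamma_zero_collapses_to_min_loss_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            w = update_w(np.array([3.0, 1.0, 1.0]), gamma=0.0)
        np.testing.assert_allclose(w, [0.0, 0.5, 0.5])

    def test_matches_qp_oracle_on_random_losses(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = int(rng.integers(2, 6))
            losses = rng.uniform(0, 5, size=v)
            gamma = float(rng.uniform(0.05, 3))
            np.testing.assert_allclose(
                update_w(losses, gamma), qp_weight_oracle(losses, gamma), atol=1e-6
            )


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_weight_update_stays_on_simplex(seed):
    r = np.random.default_rng(seed)
    w = update_w(r.uniform(0, 10, size=int(r.integers(1, 7))), float(r.uniform(0.01, 5)))
    assert abs(w.sum() - 1) < 1e-12
    assert w.min() >= 0


class TestFitAwcc:
    def test_trace_non_increasing_on_random_data(self):
        W_list, X11, X21 = random_awcc_instance(7)
        cfg = PipelineConfig(k=2, max_iter=100, tol=1e-12, seed=7)
        state = fit_awcc(W_list, X11, X21, cfg)
        tr = np.array(state.objective_trace)
        assert (tr[1:] <= tr[:-1] + 1e-9 * (1 + np.abs(tr[:-1]))).all()

    def test_identical_seeds_identical_states(self):
        W_list, X11, X21 = random_awcc_instance(2)
        cfg = PipelineConfig(k=2, max_iter=30, seed=11)
        s1 = fit_awcc(W_list, X11, X21, cfg)
        s2 = fit_awcc(W_list, X11, X21, cfg)
        np.testing.assert_array_equal(s1.G1, s2.G1)
        np.testing.assert_array_equal(s1.w, s2.w)
        assert s1.objective_trace == s2.objective_trace

    def test_k_larger_than_layer_rejected(self):
        W_list, X11, X21 = random_awcc_instance(0, g=4, m=3)
        with pytest.raises(ValueError, match="k="):
            fit_awcc(W_list, X11, X21, PipelineConfig(k=5))

    def test_orthogonality_pressure_monotone_in_beta(self):
        W_list, X11, X21 = random_awcc_instance(5, g=12, m=9, n=6, k=3, v=2)
        devs = []
        for beta in (0.1, 1.0, 10.0):
            cfg = PipelineConfig(k=3, beta=beta, max_iter=300, tol=1e-10, seed=5)
            st_ = fit_awcc(W_list, X11, X21, cfg)
            devs.append(np.linalg.norm(st_.G1.T @ st_.G1 - np.eye(3)))
        assert devs[0] >= devs[1] >= devs[2]

    def test_residuals_match_objective_decomposition(self):
        W_list, X11, X21 = random_awcc_instance(4)
        state = random_state(4, 8, 6, 5, 2, 2)
        L = view_residuals(state, W_list)
        manual = [np.linalg.norm(W - state.G1 @ S @ state.G2.T) ** 2
                  for W, S in zip(W_list, state.S_list)]
        np.testing.assert_allclose(L, manual, rtol=1e-12)
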