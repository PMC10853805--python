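"""Adaptive weighted co-clustering by non-negative tri-factorization.

Minimizes, over non-negative factors and simplex weights w,

    sum_i w_i ||W_i - G1 S_i G2^T||_F^2           (weighted tri-factorization)
  + alpha * sum_{l=1,2} ||X_l1 - G_l B||_F^2      (shared-basis expression fit)
  + beta  * sum_{l=1,2} ||G_l^T G_l - I||_F^2     (orthogonality pressure)
  + gamma * ||w||_F^2                             (weight regularization)

G1 (g x k) and G2 (m x k) are the gene / miRNA cluster-distribution matrices,
S_i the k x k harmonic matrices mapping gene clusters to miRNA clusters per
association view, B the k x n common expression basis, and w the adaptive
view weights on the probability simplex. Optimization alternates KKT-derived
multiplicative factor updates with an exact simplex-projected weight update,
so the objective is non-increasing in practice (asserted by the test suite).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig

logger = logging.getLogger(__name__)

_EPS = 1e-12  # denominator underflow guard in multiplicative updates


@dataclass
class CoClusterState:
    """Factors, harmonic matrices, basis, view weights and objective trace."""

    G1: np.ndarray  # g x k
    G2: np.ndarray  # m x k
    S_list: list[np.ndarray]  # v matrices, k x k
    B: np.ndarray  # k x n
    w: np.ndarray  # length v, on the simplex
    objective_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.G1.shape[1]

    def copy(self) -> "CoClusterState":
        return CoClusterState(
            G1=self.G1.copy(),
            G2=self.G2.copy(),
            S_list=[S.copy() for S in self.S_list],
            B=self.B.copy(),
            w=self.w.copy(),
            objective_trace=list(self.objective_trace),
        )


def _check_shapes(state, W_list, X11, X21):
    g, k = state.G1.shape
    m = state.G2.shape[0]
    n = state.B.shape[1]
    if state.G2.shape[1] != k or state.B.shape[0] != k:
        raise ValueError("factor inner dimensions disagree")
    if len(W_list) != len(state.S_list) or len(W_list) != state.w.size:
        raise ValueError("number of views disagrees across W_list, S_list and w")
    for W in W_list:
        if W.shape != (g, m):
            raise ValueError(f"association matrix shape {W.shape} != ({g}, {m})")
    for S in state.S_list:
        if S.shape != (k, k):
            raise ValueError("harmonic matrices must be k x k")
    if X11.shape != (g, n) or X21.shape != (m, n):
        raise ValueError("expression matrix shapes disagree with factors")


def objective(
    state: CoClusterState,
    W_list: list[np.ndarray],
    X11: np.ndarray,
    X21: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
) -> float:
    """Evaluate the joint objective at the current state."""
    _check_shapes(state, W_list, X11, X21)
    G1, G2, B, w = state.G1, state.G2, state.B, state.w
    k = state.k
    total = 0.0
    for wi, Wi, Si in zip(w, W_list, state.S_list):
        total += wi * np.linalg.norm(Wi - G1 @ Si @ G2.T) ** 2
    total += alpha * (
        np.linalg.norm(X11 - G1 @ B) ** 2 + np.linalg.norm(X21 - G2 @ B) ** 2
    )
    eye = np.eye(k)
    total += beta * (
        np.linalg.norm(G1.T @ G1 - eye) ** 2 + np.linalg.norm(G2.T @ G2 - eye) ** 2
    )
    total += gamma * float(w @ w)
    return float(total)


def view_residuals(state: CoClusterState, W_list: list[np.ndarray]) -> np.ndarray:
    """Per-view losses L_i = ||W_i - G1 S_i G2^T||_F^2 at the current factors."""
    G1, G2 = state.G1, state.G2
    return np.array(
        [np.linalg.norm(Wi - G1 @ Si @ G2.T) ** 2 for Wi, Si in zip(W_list, state.S_list)]
    )


def update_factors(
    state: CoClusterState,
    W_list: list[np.ndarray],
    X11: np.ndarray,
    X21: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
) -> CoClusterState:
    """One multiplicative sweep over G1, G2, {S_i}, B (w held fixed).

    Each factor is multiplied elementwise by the ratio of the positive and
    negative parts of its (halved) gradient, the standard KKT-derived rule
    for non-negative tri-factorization; non-negativity is preserved by
    construction and the objective does not increase beyond tolerance.
    """
    _check_shapes(state, W_list, X11, X21)
    st = state.copy()
    G1, G2, B, w = st.G1, st.G2, st.B, st.w

    # G1
    num = alpha * (X11 @ B.T) + 2.0 * beta * G1
    den = alpha * (G1 @ (B @ B.T)) + 2.0 * beta * (G1 @ (G1.T @ G1))
    G2tG2 = G2.T @ G2
    for wi, Wi, Si in zip(w, W_list, st.S_list):
        num += wi * (Wi @ G2 @ Si.T)
        den += wi * (G1 @ Si @ G2tG2 @ Si.T)
    G1 *= np.maximum(num, 0.0) / (den + _EPS)

    # G2
    num = alpha * (X21 @ B.T) + 2.0 * beta * G2
    den = alpha * (G2 @ (B @ B.T)) + 2.0 * beta * (G2 @ (G2.T @ G2))
    G1tG1 = G1.T @ G1
    for wi, Wi, Si in zip(w, W_list, st.S_list):
        num += wi * (Wi.T @ G1 @ Si)
        den += wi * (G2 @ Si.T @ G1tG1 @ Si)
    G2 *= np.maximum(num, 0.0) / (den + _EPS)

    # S_i (the view weight cancels from its own update)
    G1tG1 = G1.T @ G1
    G2tG2 = G2.T @ G2
    for Wi, Si in zip(W_list, st.S_list):
        Si *= np.maximum(G1.T @ Wi @ G2, 0.0) / (G1tG1 @ Si @ G2tG2 + _EPS)

    # B
    B *= np.maximum(G1.T @ X11 + G2.T @ X21, 0.0) / ((G1tG1 + G2tG2) @ B + _EPS)

    for name, G in (("G1", G1), ("G2", G2)):
        dead = np.flatnonzero(~(G > 0).any(axis=0))
        if dead.size:
            logger.warning("%s has all-zero (degenerate) cluster columns %s", name, dead)
    return st


def update_w(losses: np.ndarray, gamma: float) -> np.ndarray:
    """Exact minimizer of sum_i w_i L_i + gamma ||w||^2 on the simplex.

    Water-filling solution w_i = max(0, (lam - L_i) / (2 gamma)), equivalent
    to the Euclidean projection of -L/(2 gamma) onto the probability simplex.
    With gamma = 0 the problem is degenerate (a linear program): the weight
    collapses onto the minimal-loss view, split uniformly over ties.
    """
    losses = np.asarray(losses, dtype=float)
    if (losses < 0).any():
        raise ValueError("per-view losses must be non-negative")
    v = losses.size
    if gamma <= 0:
        warnings.warn(
            "gamma = 0 makes the weight update degenerate; "
            "returning the indicator of the minimal loss",
            stacklevel=2,
        )
        w = np.zeros(v)
        ties = np.flatnonzero(losses == losses.min())
        w[ties] = 1.0 / ties.size
        return w
    return _project_simplex(-losses / (2.0 * gamma))


def _project_simplex(y: np.ndarray) -> np.ndarray:
    """Euclidean projection onto {w : w >= 0, sum w = 1} (sort-based)."""
    u = np.sort(y)[::-1]
    css = np.cumsum(u)
    rho = np.flatnonzero(u + (1.0 - css) / np.arange(1, y.size + 1) > 0)[-1]
    lam = (1.0 - css[rho]) / (rho + 1)
    return np.maximum(y + lam, 0.0)


def fit_awcc(
    W_list: list[np.ndarray],
    X11: np.ndarray,
    X21: np.ndarray,
    config: PipelineConfig,
    seed: int | None = None,
) -> CoClusterState:
    """Alternating optimization from a seeded uniform(0,1) initialization.

    Runs multiplicative factor sweeps followed by the exact weight update
    until the relative objective change drops below ``config.tol`` or
    ``config.max_iter`` is reached. Returns the final state with the full
    objective trace (evaluated after every iteration, starting at the
    initialization).
    """
    if not W_list:
        raise ValueError("at least one association matrix is required")
    W_list = [np.asarray(W, dtype=float) for W in W_list]
    X11 = np.asarray(X11, dtype=float)
    X21 = np.asarray(X21, dtype=float)
    g, m = W_list[0].shape
    n = X11.shape[1]
    v = len(W_list)
    k = config.k
    if k > min(g, m):
        raise ValueError(f"k={k} exceeds min(g, m)={min(g, m)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = CoClusterState(
        G1=rng.uniform(size=(g, k)),
        G2=rng.uniform(size=(m, k)),
        S_list=[rng.uniform(size=(k, k)) for _ in range(v)],
        B=rng.uniform(size=(k, n)),
        w=np.full(v, 1.0 / v),
    )
    a, b, c = config.alpha, config.beta, config.gamma
    f_prev = objective(state, W_list, X11, X21, a, b, c)
    state.objective_trace.append(f_prev)
    for it in range(config.max_iter):
        state = update_factors(state, W_list, X11, X21, a, b, c)
        if c > 0:
            state.w = update_w(view_residuals(state, W_list), c)
        f = objective(state, W_list, X11, X21, a, b, c)
        if not np.isfinite(f):
            raise RuntimeError(
                f"objective became non-finite at iteration {it}; "
                f"trace so far: {state.objective_trace}"
            )
        state.objective_trace.append(f)
        if abs(f_prev - f) / max(abs(f_prev), _EPS) < config.tol:
            logger.info("converged after %d iterations (objective %.6g)", it + 1, f)
            break
        f_prev = f
    return state
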