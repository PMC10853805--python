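"""Attributed heterogeneous network construction.

The two molecular layers (genes and miRNAs) are merged into one node set:
genes occupy indices ``0..g-1``, miRNAs ``g..g+m-1``. The known bipartite
interactions ``W12`` form the off-diagonal blocks of the shared adjacency,
and each per-layer omics matrix (expression, intra-layer interactions, k-mer
sequence features) becomes one attribute view over all ``g+m`` nodes: the
owning layer carries its PCA-reduced attributes, the other layer is padded
with the constant median of that reduced block.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

_BASES = "ACGT"
_BASE_CODE = {ord(b): i for i, b in enumerate(_BASES)}


@dataclass
class HeterogeneousAdjacency:
    """Symmetric (g+m)x(g+m) adjacency with zero intra-layer blocks."""

    A: np.ndarray
    g: int
    m: int


@dataclass
class AttributeView:
    """One padded (g+m) x d_ini attribute matrix feeding one VGAE."""

    H: np.ndarray
    side: str  # "gene" or "mirna"
    source_name: str
    d_ini: int


def build_adjacency(W12: np.ndarray, validate: bool = True) -> HeterogeneousAdjacency:
    """Assemble the block adjacency ``[[0, W12], [W12.T, 0]]``."""
    W12 = np.asarray(W12, dtype=float)
    if W12.ndim != 2:
        raise ValueError("W12 must be a 2-D matrix")
    if validate and not np.isin(W12, (0.0, 1.0)).all():
        raise ValueError("W12 must be binary (entries in {0, 1})")
    g, m = W12.shape
    A = np.zeros((g + m, g + m))
    A[:g, g:] = W12
    A[g:, :g] = W12.T
    return HeterogeneousAdjacency(A=A, g=g, m=m)


def kmer_indices(k: int) -> list[str]:
    """All k-mers over ACGT in lexicographic order (column labels)."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def kmer_featurize(sequences: list[str], k: int = 4) -> np.ndarray:
    """Count overlapping k-mer windows per sequence.

    Returns an ``n_sequences x 4**k`` count matrix whose column ``j`` counts
    the j-th k-mer in lexicographic order. Windows containing any non-ACGT
    symbol are skipped; sequences shorter than ``k`` yield all-zero rows.
    """
    if not sequences:
        raise ValueError("empty sequence list")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_cols = 4**k
    out = np.zeros((len(sequences), n_cols), dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1)
    for row, seq in enumerate(sequences):
        if len(seq) < k:
            continue
        codes = np.array(
            [_BASE_CODE.get(ord(c), -1) for c in seq.upper()], dtype=np.int64
        )
        # rolling windows over the integer-coded sequence; any -1 poisons a window
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        if valid.any():
            idx = windows[valid] @ powers
            np.add.at(out[row], idx, 1)
    return out


def reduce_dim(X: np.ndarray, d_ini: int, seed: int | None = None) -> np.ndarray:
    """Top-``d_ini`` principal-component scores of the column-centered input.

    Components are ordered by decreasing explained variance, with a fixed sign
    convention: the largest-magnitude loading of each component is positive.
    Components beyond the numerical rank are padded with zero columns (with a
    warning). ``seed`` is accepted for interface symmetry; the SVD is
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if d_ini > min(n, d):
        raise ValueError(f"d_ini={d_ini} exceeds min(n_rows, n_cols)={min(n, d)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, d) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < d_ini:
        warnings.warn(
            f"requested d_ini={d_ini} exceeds numerical rank {rank}; "
            "padding remaining components with zeros",
            stacklevel=2,
        )
    scores = np.zeros((n, d_ini))
    r = min(rank, d_ini)
    for j in range(r):
        load = Vt[j]
        sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
        scores[:, j] = sign * U[:, j] * s[j]
    return scores


def build_attribute_view(
    X: np.ndarray,
    side: str,
    g: int,
    m: int,
    d_ini: int,
    seed: int | None = None,
    source_name: str = "",
) -> AttributeView:
    """Pad one per-layer attribute matrix to the full (g+m) node set.

    The owning layer's block is ``reduce_dim(X, d_ini)``; the other layer's
    block is an all-ones matrix times the scalar median over all entries of
    that reduced block. Genes are stacked above miRNAs.
    """
    X = np.asarray(X, dtype=float)
    if side not in ("gene", "mirna"):
        raise ValueError("side must be 'gene' or 'mirna'")
    own_rows = g if side == "gene" else m
    other_rows = m if side == "gene" else g
    if X.shape[0] != own_rows:
        raise ValueError(
            f"attribute matrix has {X.shape[0]} rows; expected {own_rows} for side={side!r}"
        )
    reduced = reduce_dim(X, d_ini, seed=seed)
    pad = np.full((other_rows, d_ini), np.median(reduced))
    H = np.vstack([reduced, pad]) if side == "gene" else np.vstack([pad, reduced])
    return AttributeView(H=H, side=side, source_name=source_name, d_ini=d_ini)
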