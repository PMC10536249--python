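"""Similarity network fusion (SNF) of two similarity views per node type.

The miRNA views {FSM, GSM} fuse into MM and the disease views {SSD, GSD}
into DD. Pipeline per node type:

1. row-normalize each full kernel (P = S / rowsum);
2. sparsify each into a KNN kernel (keep each row's K largest off-diagonal
   entries, renormalize the row to sum 1);
3. cross-diffuse for t iterations (parallel update):
       P1 <- K1 @ P2 @ K1.T,   P2 <- K2 @ P1_prev @ K2.T
   re-symmetrizing ((X + X.T)/2) and row-renormalizing each iterate so both
   operands remain valid transition-like kernels;
4. average the two diffused matrices and reset the diagonal to 1.

The iteration count is not a sensitive knob; diffusion contracts the two
views toward each other, and an early stop fires when they stabilize.
"""

from __future__ import annotations

import numpy as np

from .matrixio import SimilarityMatrix

__all__ = ["row_normalize", "knn_kernel", "snf_diffuse", "fuse", "fuse_mean", "snf_fuse"]


def row_normalize(S: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; all-zero rows stay zero."""
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("row_normalize requires non-negative entries")
    sums = S.sum(axis=1, keepdims=True)
    out = np.divide(S, sums, out=np.zeros_like(S), where=sums > 0)
    return out


def knn_kernel(S: np.ndarray, K: int) -> np.ndarray:
    """KNN-sparsified row-stochastic kernel.

    Row i keeps its K largest off-diagonal similarities (ties broken toward
    the lower column index), renormalized to sum 1; everything else, the
    diagonal included, is zeroed. K >= n is clamped to n - 1.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n:
        K = n - 1
    out = np.zeros_like(S)
    for i in range(n):
        row = S[i].copy()
        row[i] = -np.inf  # the node itself is never its own neighbor
        # stable sort on (-value, index): K largest, lower index wins ties
        order = np.lexsort((np.arange(n), -row))
        nbrs = order[:K]
        vals = S[i, nbrs]
        total = vals.sum()
        if total > 0:
            out[i, nbrs] = vals / total
    return out


def snf_diffuse(
    P1: np.ndarray,
    P2: np.ndarray,
    K1: np.ndarray,
    K2: np.ndarray,
    t: int = 20,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative cross-diffusion of two normalized kernels through their KNN
    kernels (parallel update; t = 0 returns the inputs unchanged).

    Each iterate is re-symmetrized and row-renormalized. Stops early once
    the largest element-wise change of both iterates falls below ``tol``.
    """
    if P1.shape != P2.shape or K1.shape != K2.shape or P1.shape != K1.shape:
        raise ValueError("all kernels must share one shape")
    if t < 0:
        raise ValueError("t must be >= 0")
    P1 = np.asarray(P1, dtype=float).copy()
    P2 = np.asarray(P2, dtype=float).copy()
    for _ in range(t):
        n1 = K1 @ P2 @ K1.T
        n2 = K2 @ P1 @ K2.T
        n1 = row_normalize((n1 + n1.T) / 2.0)
        n2 = row_normalize((n2 + n2.T) / 2.0)
        delta = max(np.abs(n1 - P1).max(), np.abs(n2 - P2).max())
        P1, P2 = n1, n2
        if delta < tol:
            break
    return P1, P2


def fuse(P1_t: np.ndarray, P2_t: np.ndarray, names: list[str], kind: str = "") -> SimilarityMatrix:
    """Average the two diffused views; diagonal reset to 1."""
    if P1_t.shape != P2_t.shape:
        raise ValueError("shape mismatch")
    M = (np.asarray(P1_t, float) + np.asarray(P2_t, float)) / 2.0
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(M, names, kind=kind)


def fuse_mean(S1: SimilarityMatrix, S2: SimilarityMatrix, kind: str = "") -> SimilarityMatrix:
    """Plain element-wise mean of two similarity views (no diffusion) —
    the fusion ablation."""
    if S1.names != S2.names:
        raise ValueError("name registries differ")
    M = (S1.values + S2.values) / 2.0
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(M, S1.names, kind=kind or f"mean({S1.kind},{S2.kind})")


def snf_fuse(
    S1: SimilarityMatrix,
    S2: SimilarityMatrix,
    K: int = 10,
    t: int = 20,
    kind: str = "",
) -> SimilarityMatrix:
    """Full SNF of two similarity views sharing a name registry."""
    if S1.names != S2.names:
        raise ValueError("name registries differ")
    P1, P2 = row_normalize(S1.values), row_normalize(S2.values)
    K1, K2 = knn_kernel(S1.values, K), knn_kernel(S2.values, K)
    P1_t, P2_t = snf_diffuse(P1, P2, K1, K2, t=t)
    # row-stochastic iterates have entries in [0,1], so the average does too
    return fuse(P1_t, P2_t, S1.names, kind=kind or f"snf({S1.kind},{S2.kind})")
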