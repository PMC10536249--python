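"""miRNA functional similarity and Gaussian interaction profile kernels.

Functional similarity (Wang-style): two miRNAs are similar to the extent
that their associated disease sets are semantically similar,

    FSM(m_i, m_j) = ( sum_{d in D(m_j)} S(d, D(m_i))
                    + sum_{d in D(m_i)} S(d, D(m_j)) ) / (|D(m_i)| + |D(m_j)|)

where S(d, Dset) = max_{d1 in Dset} SSD(d, d1). A miRNA with no known
disease gets 0 off-diagonal (and 1 on the diagonal) rather than NaN.

Gaussian interaction profile (GIP) kernel: an RBF kernel over interaction
profiles (rows of the binary association matrix A for miRNAs, columns for
diseases),

    K(i, j) = exp(-gamma * ||IP_i - IP_j||^2),
    gamma = gamma' / ( (1/n) * sum_i ||IP_i||^2 )

with the bandwidth normalized by the mean squared profile norm
(gamma' defaults to 1 for both node types).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import AssociationMatrix
from .matrixio import SimilarityMatrix

__all__ = [
    "GipConfig",
    "GipResult",
    "s_max",
    "functional_similarity",
    "functional_similarity_matrix",
    "gip_bandwidth",
    "gip_kernel",
    "gip_kernels",
]


@dataclass
class GipConfig:
    """Bandwidth priors gamma'_m (miRNA) and gamma'_d (disease)."""

    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_prime_m <= 0 or self.gamma_prime_d <= 0:
            raise ValueError("bandwidth priors must be positive")


@dataclass
class GipResult:
    gamma_m: float
    gamma_d: float
    GSM: SimilarityMatrix
    GSD: SimilarityMatrix


def s_max(disease: str, disease_set: list[str], ssd: SimilarityMatrix) -> float:
    """Best semantic match of ``disease`` within ``disease_set``."""
    if not disease_set:
        raise ValueError("empty disease set")
    idx = {n: i for i, n in enumerate(ssd.names)}
    i = idx[disease]
    return max(ssd.values[i, idx[d1]] for d1 in disease_set)


def functional_similarity(
    set_i: list[str], set_j: list[str], ssd: SimilarityMatrix
) -> float:
    """Functional similarity of two miRNAs from their disease sets."""
    m, n = len(set_i), len(set_j)
    if m + n == 0:
        return 0.0
    if m == 0 or n == 0:
        return 0.0
    total = sum(s_max(d, set_i, ssd) for d in set_j)
    total += sum(s_max(d, set_j, ssd) for d in set_i)
    return total / (m + n)


def functional_similarity_matrix(
    assoc: AssociationMatrix, ssd: SimilarityMatrix
) -> SimilarityMatrix:
    """Assemble FSM over all miRNAs of an association matrix.

    Vectorized: for each miRNA the best-match scores are row maxima of the
    SSD submatrix selected by its associated-disease columns.
    """
    if ssd.names != assoc.disease_names:
        raise ValueError("SSD disease order must match the association matrix")
    A = assoc.A.astype(bool)
    nm = assoc.n_m
    S = ssd.values
    fsm = np.eye(nm)
    cols = [np.flatnonzero(A[i]) for i in range(nm)]
    # best_match[i] has shape (n_d,): S(d, D(m_i)) for every disease d
    best = [S[:, c].max(axis=1) if c.size else None for c in cols]
    for i in range(nm):
        ci, bi = cols[i], best[i]
        if bi is None:
            continue
        for j in range(i + 1, nm):
            cj, bj = cols[j], best[j]
            if bj is None:
                continue
            num = bi[cj].sum() + bj[ci].sum()
            fsm[i, j] = fsm[j, i] = num / (ci.size + cj.size)
    return SimilarityMatrix(fsm, assoc.mirna_names, kind="FSM")


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Realized RBF bandwidth: prior over mean squared profile norm."""
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = (profiles**2).sum(axis=1).mean()
    if mean_sq == 0:
        raise ValueError("all profiles are zero: bandwidth undefined")
    return gamma_prime / mean_sq


def gip_kernel(profiles: np.ndarray, gamma: float, names: list[str], kind: str = "GIP") -> SimilarityMatrix:
    """RBF kernel matrix exp(-gamma * ||IP_i - IP_j||^2) over profiles."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    profiles = np.asarray(profiles, dtype=float)
    sq = (profiles**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(K, names, kind=kind)


def gip_kernels(assoc: AssociationMatrix, cfg: GipConfig | None = None) -> GipResult:
    """GSM (over miRNAs, from rows of A) and GSD (over diseases, from
    columns of A)."""
    cfg = cfg or GipConfig()
    gamma_m = gip_bandwidth(assoc.A, cfg.gamma_prime_m)
    gamma_d = gip_bandwidth(assoc.A.T, cfg.gamma_prime_d)
    gsm = gip_kernel(assoc.A, gamma_m, assoc.mirna_names, kind="GSM")
    gsd = gip_kernel(assoc.A.T, gamma_d, assoc.disease_names, kind="GSD")
    return GipResult(gamma_m=gamma_m, gamma_d=gamma_d, GSM=gsm, GSD=gsd)
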