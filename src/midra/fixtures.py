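"""Synthetic desk-scale inputs with the statistical structure the method
assumes.

Two generators emulate the real inputs without any download:

* :func:`generate_hierarchy` — a rooted, level-structured random DAG over
  the disease names, with a fraction of nodes given a second parent so the
  multi-path semantic-contribution logic is exercised.
* :func:`generate_associations` — a planted latent-factor bipartite model:
  non-negative factors U (miRNAs) and V (diseases) give a true association
  propensity logistic(scale * (U V^T centered)); the observed positives are
  the top ``density`` fraction of pairs, with a small fraction of labels
  flipped as noise. Low-rank structure is essential: the method's premise is
  that functionally similar miRNAs associate with semantically similar
  diseases, so a structureless (Erdos-Renyi) matrix would make every
  predictor equal to chance.

Both are pure functions of (spec, seed): reruns are byte-identical.

:func:`fig2_fixture` builds a small worked breast-neoplasms-style ancestor
DAG (six MeSH-like labels; the edge topology is this package's documented
choice) used by the semantic-similarity tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .assoc import AssociationMatrix, AssociationTable
from .matrixio import SimilarityMatrix
from .semantics import DiseaseHierarchy

__all__ = [
    "FixtureSpec",
    "generate_hierarchy",
    "hierarchy_lines",
    "generate_associations",
    "AssociationFixture",
    "fig2_fixture",
    "FIG2_EDGES",
]


@dataclass
class FixtureSpec:
    """Shape and noise parameters of the synthetic study system.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 60 miRNAs x 40 diseases, rank-4 latent structure, 15% association
    density, 2% label noise, a depth-4 branching-3 disease hierarchy.
    """

    n_m: int = 60
    n_d: int = 40
    n_latent: int = 4
    density: float = 0.15
    noise: float = 0.02
    dag_depth: int = 4
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if min(self.n_m, self.n_d, self.n_latent) < 2:
            raise ValueError("all counts must be >= 2")


def _disease_names(n: int) -> list[str]:
    return [f"disease_{i:03d}" for i in range(n)]


def _mirna_names(n: int) -> list[str]:
    return [f"mir-{i:03d}" for i in range(n)]


def generate_hierarchy(spec: FixtureSpec) -> DiseaseHierarchy:
    """Random rooted DAG over the spec's disease names.

    Diseases are assigned to levels 0..dag_depth (level 0 is the single
    root); each non-root node gets one parent from the level above and, with
    probability 0.25, a second parent from any strictly higher level —
    exercising the max-over-paths semantic contribution.
    """
    rng = np.random.default_rng(spec.seed)
    names = _disease_names(spec.n_d)
    depth = max(1, spec.dag_depth)
    # sizes per level grow with branching, clipped to fit n_d
    levels: list[list[str]] = [[names[0]]]
    idx = 1
    lvl = 1
    while idx < spec.n_d:
        size = min(len(levels[-1]) * spec.dag_branching, spec.n_d - idx)
        if lvl >= depth:  # everything left goes on the last level
            size = spec.n_d - idx
        levels.append(names[idx : idx + size])
        idx += size
        lvl += 1
    parents: dict[str, set[str]] = {names[0]: set()}
    for li in range(1, len(levels)):
        for d in levels[li]:
            p = levels[li - 1][rng.integers(len(levels[li - 1]))]
            parents[d] = {p}
            if li >= 2 and rng.random() < 0.25:
                lj = int(rng.integers(li))  # a strictly higher level
                q = levels[lj][rng.integers(len(levels[lj]))]
                parents[d].add(q)
    return DiseaseHierarchy(parents)


def hierarchy_lines(h: DiseaseHierarchy) -> str:
    """Serialize a hierarchy in the child<TAB>parent dialect."""
    out = []
    for d in h.diseases:
        ps = sorted(h.parents[d])
        if not ps:
            out.append(d)
        for p in ps:
            out.append(f"{d}\t{p}")
    return "\n".join(out) + "\n"


@dataclass
class AssociationFixture:
    """Everything the planted generator knows about its system."""

    assoc: AssociationMatrix
    table: AssociationTable
    propensity: np.ndarray  # (n_m, n_d) true association probability
    future_positives: np.ndarray  # (h, 2) held-out high-propensity pairs
    mirna_similarity: SimilarityMatrix  # latent-factor cosine (test stand-in)
    disease_similarity: SimilarityMatrix

    def association_tsv(self) -> str:
        return "".join(f"{m}\t{d}\n" for m, d in self.table.records)


def _cosine(M: np.ndarray, names: list[str], kind: str) -> SimilarityMatrix:
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    U = M / np.where(norms > 0, norms, 1.0)
    C = np.clip(U @ U.T, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return SimilarityMatrix((C + C.T) / 2, names, kind=kind)


def generate_associations(spec: FixtureSpec) -> AssociationFixture:
    """Sample the planted latent-factor association fixture.

    With noise = 0 the observed matrix has exactly
    ``round(density * n_m * n_d)`` positives (the top-propensity pairs).
    """
    total = spec.n_m * spec.n_d
    n_pos = int(round(spec.density * total))
    if n_pos < 10:
        raise ValueError("density too low: need >= 10 planted positives")
    rng = np.random.default_rng(spec.seed)
    U = rng.gamma(shape=2.0, scale=1.0, size=(spec.n_m, spec.n_latent))
    V = rng.gamma(shape=2.0, scale=1.0, size=(spec.n_d, spec.n_latent))
    raw = U @ V.T
    z = (raw - raw.mean()) / raw.std()
    propensity = 1.0 / (1.0 + np.exp(-2.0 * z))

    flat = propensity.ravel()
    order = np.argsort(-flat, kind="mergesort")
    A = np.zeros(total)
    A[order[:n_pos]] = 1.0
    # held-out "future positives": the next 5% strongest non-observed pairs
    n_future = max(1, n_pos // 20)
    future = order[n_pos : n_pos + n_future]

    if spec.noise > 0:
        flips = rng.random(total) < spec.noise
        flips[future] = False  # held-out pairs stay unobserved
        A[flips] = 1.0 - A[flips]
    A = A.reshape(spec.n_m, spec.n_d)

    mirnas = _mirna_names(spec.n_m)
    diseases = _disease_names(spec.n_d)
    records = [
        (mirnas[i], diseases[j]) for i, j in np.argwhere(A == 1)
    ]
    table = AssociationTable(records)
    assoc = AssociationMatrix(A, mirnas, diseases)
    fut = np.column_stack(np.unravel_index(future, (spec.n_m, spec.n_d)))
    return AssociationFixture(
        assoc=assoc,
        table=table,
        propensity=propensity,
        future_positives=fut,
        mirna_similarity=_cosine(U, mirnas, "FSM-standin"),
        disease_similarity=_cosine(V, diseases, "SSD-standin"),
    )


# Documented edge topology of the worked breast-neoplasms-style DAG
# (child -> parents). Six nodes: the target plus its five ancestors.
FIG2_EDGES: dict[str, set[str]] = {
    "Breast Neoplasms": {"Breast Diseases", "Neoplasms by Site"},
    "Breast Diseases": {"Skin Diseases"},
    "Skin Diseases": {"Skin and Connective Tissue Diseases"},
    "Neoplasms by Site": {"Neoplasms"},
    "Neoplasms": set(),
    "Skin and Connective Tissue Diseases": set(),
}


def fig2_fixture() -> DiseaseHierarchy:
    """The six-node breast-neoplasms ancestor hierarchy (synthetic edge
    topology, documented in FIG2_EDGES)."""
    return DiseaseHierarchy({k: set(v) for k, v in FIG2_EDGES.items()})


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the association TSV and hierarchy file for a spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fix = generate_associations(spec)
    h = generate_hierarchy(spec)
    assoc_path = out / "associations.tsv"
    hier_path = out / "hierarchy.tsv"
    assoc_path.write_text(fix.association_tsv())
    hier_path.write_text(hierarchy_lines(h))
    return {"assoc": assoc_path, "hierarchy": hier_path}
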