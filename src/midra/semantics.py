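"""Disease semantic similarity from per-disease ancestor DAGs.

Each disease in a MeSH-style hierarchy induces a directed acyclic graph
DAG[d] = (d, T[d], E[d]) where T[d] contains d and all of its ancestors and
E[d] the parent->child edges among them. Two complementary per-node
contribution scores are combined:

* D1 (position-based): D1(d) = 1 for the disease itself; for an ancestor n,
  D1(n) = max over children c of n within the DAG of delta * D1(c), i.e.
  delta raised to the shortest directed path length from n down to d. delta
  is the semantic contribution factor (default 0.5), a per-generation decay.
* D2 (specificity-based): D2(n) = -log(fraction of all disease DAGs that
  contain n) — rarer ancestors are more informative. The log base cancels in
  the similarity ratio, so the choice (default: natural log) is cosmetic.

Each score yields a semantic value SSV(d) = sum of contributions over T[d],
and a pairwise similarity

    SSD_k(i, j) = sum_{n in T[i] & T[j]} (Dk_i(n) + Dk_j(n)) / (SSV_k(i) + SSV_k(j))

The final semantic similarity is the mean of the two variants. Diseases
absent from the hierarchy get similarity 0 off-diagonal and 1 on the
diagonal; the Gaussian interaction profile kernel supplies their signal
after network fusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrixio import SimilarityMatrix

__all__ = [
    "SemanticConfig",
    "DiseaseDAG",
    "DiseaseHierarchy",
    "parse_hierarchy",
    "d1_contribution",
    "semantic_value_1",
    "ssd1_pair",
    "d2_contribution",
    "semantic_value_2",
    "ssd2_pair",
    "semantic_similarity_matrices",
    "combined_ssd",
]


@dataclass
class SemanticConfig:
    """Tunables for semantic similarity.

    delta: per-generation semantic contribution factor, in (0, 1).
    log_base: base of the specificity log; the SSD2 ratio is base-invariant.
    universe: denominator of the specificity fraction (number of diseases);
        ``None`` means the hierarchy size.
    """

    delta: float = 0.5
    log_base: float = math.e
    universe: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")


@dataclass
class DiseaseDAG:
    """Ancestor DAG of one disease: the disease, its ancestor closure, and
    the parent map restricted to that closure."""

    target: str
    nodes: frozenset[str]
    parents: dict[str, frozenset[str]]  # node -> parents within the DAG

    def children_of(self, node: str) -> list[str]:
        """Children of ``node`` within this DAG (nodes it points toward)."""
        return [c for c in self.nodes if node in self.parents.get(c, ())]


class DiseaseHierarchy:
    """A global disease hierarchy (name -> parent names), acyclic."""

    def __init__(self, parents: dict[str, set[str]]):
        # close over parent names that never appear as children
        all_names = set(parents)
        for ps in parents.values():
            all_names |= ps
        self.parents: dict[str, frozenset[str]] = {
            n: frozenset(parents.get(n, set())) for n in sorted(all_names)
        }
        self._check_acyclic()
        self._dag_cache: dict[str, DiseaseDAG] = {}

    def _check_acyclic(self) -> None:
        # Kahn's algorithm over child->parent edges
        indeg = {n: len(ps) for n, ps in self.parents.items()}
        children: dict[str, list[str]] = {n: [] for n in self.parents}
        for n, ps in self.parents.items():
            for p in ps:
                children[p].append(n)
        stack = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while stack:
            p = stack.pop()
            seen += 1
            for c in children[p]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if seen != len(self.parents):
            raise ValueError("hierarchy contains a cycle")

    @property
    def diseases(self) -> list[str]:
        return list(self.parents)

    def __contains__(self, name: str) -> bool:
        return name in self.parents

    def dag(self, disease: str) -> DiseaseDAG:
        """The ancestor DAG of ``disease`` (includes the disease itself)."""
        if disease not in self.parents:
            raise KeyError(f"disease {disease!r} not in hierarchy")
        if disease in self._dag_cache:
            return self._dag_cache[disease]
        nodes = {disease}
        frontier = [disease]
        while frontier:
            n = frontier.pop()
            for p in self.parents[n]:
                if p not in nodes:
                    nodes.add(p)
                    frontier.append(p)
        restricted = {n: frozenset(p for p in self.parents[n] if p in nodes) for n in nodes}
        dag = DiseaseDAG(disease, frozenset(nodes), restricted)
        self._dag_cache[disease] = dag
        return dag

    def dag_membership_counts(self) -> dict[str, int]:
        """For each node, the number of disease DAGs that contain it."""
        counts: dict[str, int] = {n: 0 for n in self.parents}
        for d in self.parents:
            for n in self.dag(d).nodes:
                counts[n] += 1
        return counts


def parse_hierarchy(path: str | Path, dialect: str = "auto") -> DiseaseHierarchy:
    """Parse a disease hierarchy file.

    Two dialects are accepted (tab-separated, ``#`` comments skipped):

    * ``parent``: lines of ``child<TAB>parent``; a line with a single field
      declares a root disease with no parent.
    * ``mesh``: lines of ``disease<TAB>tree-number`` (dot-separated numeric
      components, e.g. ``C04.588.180``); a disease may own several tree
      numbers and its DAG is the union of the ancestor paths of all of them.

    ``auto`` sniffs the dialect from the first data line's second field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines: list[list[str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in raw.split("\t")]
            if not fields[0]:
                raise ValueError(f"{path}:{lineno}: empty disease name")
            lines.append(fields)
    if dialect == "auto":
        dialect = "parent"
        for fields in lines:
            if len(fields) >= 2 and fields[1]:
                tokens = fields[1].split(".")
                if all(t and all(ch.isdigit() or ch.isalpha() for ch in t) for t in tokens) and (
                    len(tokens) > 1 or fields[1][:1].isalpha() and fields[1][1:].isdigit()
                ):
                    dialect = "mesh"
                break
    if dialect == "parent":
        parents: dict[str, set[str]] = {}
        for fields in lines:
            child = fields[0]
            parents.setdefault(child, set())
            if len(fields) >= 2 and fields[1]:
                parents[child].add(fields[1])
        return DiseaseHierarchy(parents)
    if dialect == "mesh":
        owner: dict[str, str] = {}  # tree number -> disease name
        trees: dict[str, list[str]] = {}
        for fields in lines:
            if len(fields) < 2 or not fields[1]:
                trees.setdefault(fields[0], [])
                continue
            owner[fields[1]] = fields[0]
            trees.setdefault(fields[0], []).append(fields[1])
        parents = {d: set() for d in trees}
        for d, tns in trees.items():
            for tn in tns:
                parts = tn.split(".")
                if len(parts) > 1:
                    parent_tn = ".".join(parts[:-1])
                    if parent_tn in owner:
                        parents[d].add(owner[parent_tn])
        return DiseaseHierarchy(parents)
    raise ValueError(f"unknown hierarchy dialect {dialect!r}")


def d1_contribution(dag: DiseaseDAG, node: str, cfg: SemanticConfig | None = None) -> float:
    """Position-based contribution of ``node`` to the DAG's target disease.

    Equals ``delta ** (shortest directed path length node -> target)``;
    computed by the max-over-children recursion it is defined by.
    """
    cfg = cfg or SemanticConfig()
    if node not in dag.nodes:
        raise KeyError(f"{node!r} not in DAG of {dag.target!r}")
    memo: dict[str, float] = {dag.target: 1.0}

    def rec(n: str) -> float:
        if n in memo:
            return memo[n]
        kids = dag.children_of(n)
        if not kids:  # only the target has no children on a path toward it
            raise ValueError(f"{n!r} has no path to {dag.target!r} in its DAG")
        val = max(cfg.delta * rec(c) for c in kids)
        memo[n] = val
        return val

    return rec(node)


def semantic_value_1(dag: DiseaseDAG, cfg: SemanticConfig | None = None) -> float:
    """SSV1: total D1 contribution over the ancestor closure (>= 1)."""
    cfg = cfg or SemanticConfig()
    return sum(d1_contribution(dag, n, cfg) for n in dag.nodes)


def ssd1_pair(
    dag_i: DiseaseDAG, dag_j: DiseaseDAG, cfg: SemanticConfig | None = None
) -> float:
    """Position-based semantic similarity of two diseases, in [0, 1]."""
    cfg = cfg or SemanticConfig()
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    num = sum(d1_contribution(dag_i, n, cfg) + d1_contribution(dag_j, n, cfg) for n in shared)
    den = semantic_value_1(dag_i, cfg) + semantic_value_1(dag_j, cfg)
    return num / den


def d2_contribution(
    node: str,
    counts: dict[str, int],
    universe: int,
    log_base: float = math.e,
) -> float:
    """Specificity-based contribution: -log(DAG count / universe size)."""
    c = counts.get(node, 0)
    if c <= 0:
        raise ValueError(f"{node!r} appears in no DAG")
    if universe <= 0:
        raise ValueError("universe must be positive")
    return -math.log(c / universe) / math.log(log_base)


def semantic_value_2(
    dag: DiseaseDAG,
    counts: dict[str, int],
    universe: int,
    cfg: SemanticConfig | None = None,
) -> float:
    cfg = cfg or SemanticConfig()
    return sum(d2_contribution(n, counts, universe, cfg.log_base) for n in dag.nodes)


def ssd2_pair(
    dag_i: DiseaseDAG,
    dag_j: DiseaseDAG,
    counts: dict[str, int],
    universe: int,
    cfg: SemanticConfig | None = None,
) -> float:
    """Specificity-based semantic similarity; 0/0 (all-uninformative DAGs)
    resolves to 1 on the diagonal and 0 off it."""
    cfg = cfg or SemanticConfig()
    shared = dag_i.nodes & dag_j.nodes
    # D2 is DAG-independent, so each shared node contributes its score twice
    num = sum(2.0 * d2_contribution(n, counts, universe, cfg.log_base) for n in shared)
    den = semantic_value_2(dag_i, counts, universe, cfg) + semantic_value_2(
        dag_j, counts, universe, cfg
    )
    if den == 0.0:
        return 1.0 if dag_i.target == dag_j.target else 0.0
    return num / den


def semantic_similarity_matrices(
    hierarchy: DiseaseHierarchy,
    diseases: list[str],
    cfg: SemanticConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """SSD1 and SSD2 matrices over ``diseases`` (hierarchy-absent diseases
    get identity rows)."""
    cfg = cfg or SemanticConfig()
    n = len(diseases)
    counts = hierarchy.dag_membership_counts()
    universe = cfg.universe if cfg.universe is not None else len(hierarchy.diseases)
    dags = {d: hierarchy.dag(d) for d in diseases if d in hierarchy}
    # cache per-disease D1 maps and semantic values
    d1_maps = {
        d: {n_: d1_contribution(g, n_, cfg) for n_ in g.nodes} for d, g in dags.items()
    }
    ssv1 = {d: sum(m.values()) for d, m in d1_maps.items()}
    d2_maps = {
        d: {n_: d2_contribution(n_, counts, universe, cfg.log_base) for n_ in g.nodes}
        for d, g in dags.items()
    }
    ssv2 = {d: sum(m.values()) for d, m in d2_maps.items()}

    S1 = np.eye(n)
    S2 = np.eye(n)
    for i in range(n):
        di = diseases[i]
        if di not in dags:
            continue
        for j in range(i, n):
            dj = diseases[j]
            if dj not in dags:
                continue
            shared = dags[di].nodes & dags[dj].nodes
            if shared:
                num1 = sum(d1_maps[di][s] + d1_maps[dj][s] for s in shared)
                S1[i, j] = S1[j, i] = num1 / (ssv1[di] + ssv1[dj])
                num2 = sum(d2_maps[di][s] + d2_maps[dj][s] for s in shared)
                den2 = ssv2[di] + ssv2[dj]
                if den2 > 0:
                    S2[i, j] = S2[j, i] = num2 / den2
                else:
                    S2[i, j] = S2[j, i] = 1.0 if i == j else 0.0
            else:
                S1[i, j] = S1[j, i] = 0.0
                S2[i, j] = S2[j, i] = 0.0
        S1[i, i] = 1.0
        S2[i, i] = 1.0
    return (
        SimilarityMatrix(S1, diseases, kind="SSD1"),
        SimilarityMatrix(S2, diseases, kind="SSD2"),
    )


def combined_ssd(
    hierarchy: DiseaseHierarchy,
    diseases: list[str],
    cfg: SemanticConfig | None = None,
) -> SimilarityMatrix:
    """Final disease semantic similarity: element-wise mean of the two
    variants."""
    s1, s2 = semantic_similarity_matrices(hierarchy, diseases, cfg)
    return SimilarityMatrix((s1.values + s2.values) / 2.0, diseases, kind="SSD")
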