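"""Cross-validation harness, metrics, DropEdge sweep, and ablations.

The k known-association folds partition the positive pairs; per fold the
test positives are masked out of A and every similarity that depends on A —
the GIP kernels, the functional similarity FSM (through the per-miRNA
disease sets) and the SNF fusion — is recomputed from the masked matrix, so
no test label can leak into training. The disease semantic similarity SSD
depends only on the hierarchy and is computed once.

Metrics: ROC AUC as the tie-averaged rank statistic (the probability that a
random positive outranks a random negative, ties counting 1/2), AUPR by
trapezoid over the stepwise precision-recall curve, and accuracy / recall /
F1 at the 0.5 threshold. Test negatives are sampled 1:1 with test positives
by default; exhaustive ranking over all unknown pairs is available.

Ablation variants:

* ``full``       — SNF fusion + DropEdge + jumping knowledge;
* ``mean_fusion``— similarity views averaged instead of SNF-diffused;
* ``no_dropedge``— drop rate forced to 0;
* ``plain_gcn``  — last-layer representations only (no JK aggregation).

Third-party scorers can enter the same harness through the ``scorer``
plug-in: any callable (A_train, fold context) -> dense score matrix.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .assoc import AssociationMatrix
from .config import RunConfig
from .gcn import build_hetero_graph, train
from .kernels import functional_similarity_matrix, gip_kernels
from .matrixio import SimilarityMatrix
from .semantics import DiseaseHierarchy, combined_ssd
from .snf import fuse_mean, snf_fuse

__all__ = [
    "VARIANTS",
    "FoldSplit",
    "FoldMetrics",
    "MetricsReport",
    "kfold_split",
    "auc",
    "aupr",
    "pr_curve",
    "roc_curve",
    "threshold_metrics",
    "run_cv",
    "drop_rate_sweep",
]

VARIANTS = ("full", "mean_fusion", "no_dropedge", "plain_gcn")


# --------------------------------------------------------------------------
# fold construction
# --------------------------------------------------------------------------

@dataclass
class FoldSplit:
    """k folds of positive pairs plus matched test-negative samples."""

    pos_folds: list[np.ndarray]  # each (f, 2) int array of (i, j)
    neg_folds: list[np.ndarray]
    k: int
    seed: int


def kfold_split(assoc: AssociationMatrix, k: int, seed: int = 0) -> FoldSplit:
    """Shuffle the positives and partition into k folds (sizes differ by
    <= 1); per fold, sample an equal number of never-associated pairs as
    test negatives (without replacement across folds)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    pos = np.argwhere(assoc.A == 1)
    if len(pos) < k:
        raise ValueError(f"need at least k={k} positives, have {len(pos)}")
    rng = np.random.default_rng(seed)
    pos = pos[rng.permutation(len(pos))]
    pos_folds = [pos[f::k] for f in range(k)]

    neg = np.argwhere(assoc.A == 0)
    if len(neg) < len(pos):
        raise ValueError("not enough unknown pairs for 1:1 test negatives")
    neg = neg[rng.permutation(len(neg))]
    neg_folds = []
    off = 0
    for f in range(k):
        size = len(pos_folds[f])
        neg_folds.append(neg[off : off + size])
        off += size
    return FoldSplit(pos_folds=pos_folds, neg_folds=neg_folds, k=k, seed=seed)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney statistic with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for AUC")
    order = np.argsort(scores, kind="mergesort")
    s = scores[order]
    ranks = np.empty(len(s))
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        ranks[i : j + 1] = (i + j) / 2.0 + 1.0  # average 1-based rank
        i = j + 1
    pos_rank_sum = ranks[labels[order] == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise precision-recall points at each distinct score threshold,
    descending; prepended with the (recall=0, precision=1) anchor."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("need at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # indices where a threshold group ends (distinct score values)
    distinct = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[ends]
    fp = np.cumsum(1 - y)[ends]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return np.concatenate([[0.0], recall]), np.concatenate([[1.0], precision])


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points at each distinct threshold, from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for a ROC curve")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([distinct, [len(s) - 1]])
    tpr = np.cumsum(y)[ends] / n_pos
    fpr = np.cumsum(1 - y)[ends] / n_neg
    return np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by the trapezoid rule."""
    recall, precision = pr_curve(scores, labels)
    return float(np.trapezoid(precision, recall))


def threshold_metrics(
    scores: np.ndarray, labels: np.ndarray, thr: float = 0.5
) -> tuple[float, float, float]:
    """(accuracy, recall, F1) at a hard threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = (scores >= thr).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = float((pred == labels).mean())
    rec = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, rec, f1


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    auc: float
    aupr: float
    accuracy: float
    recall: float
    f1: float
    roc: tuple[list[float], list[float]] = field(default_factory=lambda: ([], []))
    pr: tuple[list[float], list[float]] = field(default_factory=lambda: ([], []))
    leaked_test_edges: int = 0


@dataclass
class MetricsReport:
    folds: list[FoldMetrics]
    variant: str
    k: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean([f.aupr for f in self.folds]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def mean_recall(self) -> float:
        return float(np.mean([f.recall for f in self.folds]))

    @property
    def mean_f1(self) -> float:
        return float(np.mean([f.f1 for f in self.folds]))

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "k": self.k,
            "seed": self.seed,
            "folds": [dataclasses.asdict(f) for f in self.folds],
            "mean": {
                "auc": self.mean_auc,
                "aupr": self.mean_aupr,
                "accuracy": self.mean_accuracy,
                "recall": self.mean_recall,
                "f1": self.mean_f1,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MetricsReport":
        d = json.loads(Path(path).read_text())
        folds = [
            FoldMetrics(
                auc=f["auc"],
                aupr=f["aupr"],
                accuracy=f["accuracy"],
                recall=f["recall"],
                f1=f["f1"],
                roc=(list(f["roc"][0]), list(f["roc"][1])),
                pr=(list(f["pr"][0]), list(f["pr"][1])),
                leaked_test_edges=f.get("leaked_test_edges", 0),
            )
            for f in d["folds"]
        ]
        return cls(folds=folds, variant=d["variant"], k=d["k"], seed=d["seed"])


def _variant_train_config(config: RunConfig, variant: str):
    tc = config.train
    if variant == "no_dropedge":
        tc = replace(tc, drop_rate=0.0)
    elif variant == "plain_gcn":
        tc = replace(tc, jk_mode="none")
    elif variant not in ("full", "mean_fusion"):
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return tc


def fold_similarities(
    A_train: AssociationMatrix,
    ssd: SimilarityMatrix,
    config: RunConfig,
    variant: str,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """MM and DD for one fold, recomputed from the masked matrix."""
    fsm = functional_similarity_matrix(A_train, ssd)
    gip = gip_kernels(A_train, config.gip)
    if variant == "mean_fusion":
        mm = fuse_mean(fsm, gip.GSM, kind="MM")
        dd = fuse_mean(ssd, gip.GSD, kind="DD")
    else:
        mm = snf_fuse(fsm, gip.GSM, K=config.snf_k, t=config.snf_t, kind="MM")
        dd = snf_fuse(ssd, gip.GSD, K=config.snf_k, t=config.snf_t, kind="DD")
    return mm, dd


def run_cv(
    assoc: AssociationMatrix,
    hierarchy: DiseaseHierarchy,
    config: RunConfig,
    variant: str = "full",
    k: int = 5,
    seed: int = 0,
    exhaustive_negatives: bool = False,
    scorer: Callable[[AssociationMatrix, dict], np.ndarray] | None = None,
    keep_curves: bool = True,
) -> MetricsReport:
    """k-fold cross-validation of one model variant.

    ``scorer`` overrides the built-in model: it receives the fold's masked
    association matrix plus a context dict (``ssd``, ``config``, ``seed``)
    and must return an (n_m, n_d) score matrix.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    split = kfold_split(assoc, k, seed)
    ssd = combined_ssd(hierarchy, assoc.disease_names, config.semantic)
    tc = _variant_train_config(config, variant)

    folds: list[FoldMetrics] = []
    for f in range(k):
        test_pos = split.pos_folds[f]
        A_train = assoc.A.copy()
        A_train[test_pos[:, 0], test_pos[:, 1]] = 0.0
        masked = AssociationMatrix(A_train, assoc.mirna_names, assoc.disease_names)

        try:
            if scorer is not None:
                scores = scorer(masked, {"ssd": ssd, "config": config, "seed": seed + f})
                leaked = 0
            else:
                mm, dd = fold_similarities(masked, ssd, config, variant)
                fold_tc = replace(tc, seed=tc.seed + f)
                graph = build_hetero_graph(mm, dd, masked, fold_tc)
                # leakage instrumentation: test positives must not be edges
                cross = graph.W[: masked.n_m, masked.n_m :]
                leaked = int((cross[test_pos[:, 0], test_pos[:, 1]] > 0).sum())
                if leaked:
                    raise RuntimeError(f"{leaked} test positives leaked into the graph")
                result = train(graph, fold_tc)
                scores = result.scores
        except Exception as exc:
            raise RuntimeError(f"fold {f} failed: {exc}") from exc

        if exhaustive_negatives:
            neg_mask = assoc.A == 0
            ni, nj = np.nonzero(neg_mask)
            test_neg = np.column_stack([ni, nj])
        else:
            test_neg = split.neg_folds[f]
        y = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])
        s = np.concatenate(
            [scores[test_pos[:, 0], test_pos[:, 1]], scores[test_neg[:, 0], test_neg[:, 1]]]
        )
        acc, rec, f1 = threshold_metrics(s, y)
        fpr, tpr = roc_curve(s, y)
        recall, precision = pr_curve(s, y)
        folds.append(
            FoldMetrics(
                auc=auc(s, y),
                aupr=aupr(s, y),
                accuracy=acc,
                recall=rec,
                f1=f1,
                roc=(fpr.tolist(), tpr.tolist()) if keep_curves else ([], []),
                pr=(recall.tolist(), precision.tolist()) if keep_curves else ([], []),
                leaked_test_edges=leaked,
            )
        )
    return MetricsReport(folds=folds, variant=variant, k=k, seed=seed)


def drop_rate_sweep(
    assoc: AssociationMatrix,
    hierarchy: DiseaseHierarchy,
    config: RunConfig,
    rates: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8),
    k: int = 5,
    seed: int = 0,
) -> list[MetricsReport]:
    """One CV report per DropEdge rate, same folds/seed across rates."""
    reports = []
    for p in rates:
        if not 0 <= p < 1:
            raise ValueError("rates must lie in [0, 1)")
        cfg_p = replace(config, train=replace(config.train, drop_rate=p))
        reports.append(run_cv(assoc, hierarchy, cfg_p, variant="full", k=k, seed=seed))
    return reports
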