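"""Metric oracles, fold hygiene, and the cross-validation harness."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from midra.assoc import AssociationMatrix
from midra.config import RunConfig
from midra.evaluation import (
    MetricsReport,
    auc,
    aupr,
    kfold_split,
    pr_curve,
    roc_curve,
    run_cv,
    threshold_metrics,
)
from midra.fixtures import FixtureSpec, generate_associations, generate_hierarchy
from midra.gcn import TrainConfig


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def brute_force_auc(scores, labels):
    """All-pairs concordance count, ties 1/2 (exact rational arithmetic)."""
    from fractions import Fraction

    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    num = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                num += 1
            elif p == q:
                num += Fraction(1, 2)
    return num / (len(pos) * len(neg))


def brute_force_pr_points(scores, labels):
    """Stepwise PR points by direct counting at each distinct threshold."""
    pts = [(0.0, 1.0)]
    n_pos = sum(labels)
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 0)
        pts.append((tp / n_pos, tp / (tp + fp)))
    return pts


def brute_force_aupr(scores, labels):
    pts = brute_force_pr_points(scores, labels)
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p1 + p0) / 2
    return area


def test_auc_hand_case_and_edge_cases():
    assert auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)
    assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5  # all ties
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [1, 1])


def test_auc_matches_brute_force_and_sklearn():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(5, 200))
        # coarse grid forces ties
        scores = rng.integers(0, 10, size=n) / 10.0
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        expected = float(brute_force_auc(scores.tolist(), labels.tolist()))
        assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_aupr_matches_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(5, 200))
        scores = rng.integers(0, 10, size=n) / 10.0
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        if labels.sum() == n:
            labels[0] = 0
        assert aupr(scores, labels) == pytest.approx(brute_force_aupr(scores.tolist(), labels.tolist()), abs=1e-12)


def test_curves_shapes_and_monotonicity():
    scores = [0.9, 0.7, 0.7, 0.3, 0.1]
    labels = [1, 1, 0, 0, 1]
    fpr, tpr = roc_curve(scores, labels)
    assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
    recall, precision = pr_curve(scores, labels)
    assert recall[0] == 0 and precision[0] == 1 and recall[-1] == 1
    assert (np.diff(recall) >= 0).all()


def test_threshold_metrics():
    scores = [0.9, 0.6, 0.4, 0.1]
    labels = [1, 0, 1, 0]
    acc, rec, f1 = threshold_metrics(scores, labels, 0.5)
    # predictions: 1 1 0 0 -> TP=1 FP=1 FN=1 TN=1
    assert acc == 0.5 and rec == 0.5
    assert f1 == pytest.approx(0.5)


# --------------------------------------------------------------------------
# folds and the harness
# --------------------------------------------------------------------------

def test_kfold_partition_properties(assoc_fixture):
    am = assoc_fixture.assoc
    split = kfold_split(am, 5, seed=3)
    all_pos = np.concatenate(split.pos_folds)
    assert len(all_pos) == int(am.A.sum())
    seen = {tuple(p) for p in all_pos}
    assert len(seen) == len(all_pos)  # disjoint folds
    sizes = [len(f) for f in split.pos_folds]
    assert max(sizes) - min(sizes) <= 1
    # negatives are genuinely unknown pairs
    for nf in split.neg_folds:
        assert (am.A[nf[:, 0], nf[:, 1]] == 0).all()
    # determinism
    split2 = kfold_split(am, 5, seed=3)
    for a, b in zip(split.pos_folds, split2.pos_folds):
        assert np.array_equal(a, b)


def test_kfold_rejects_bad_k():
    am = AssociationMatrix(np.eye(3), ["m0", "m1", "m2"], ["d0", "d1", "d2"])
    with pytest.raises(ValueError):
        kfold_split(am, 1)
    with pytest.raises(ValueError):
        kfold_split(am, 5)  # only 3 positives


@pytest.fixture(scope="module")
def small_cv_setup():
    spec = FixtureSpec(n_m=30, n_d=20, density=0.2, noise=0.0, seed=5)
    fix = generate_associations(spec)
    hier = generate_hierarchy(spec)
    cfg = RunConfig(train=TrainConfig(epochs=60, layer_sizes=(32, 32), seed=2))
    return fix, hier, cfg


def test_run_cv_reports_and_leakage_counter(small_cv_setup):
    fix, hier, cfg = small_cv_setup
    rep = run_cv(fix.assoc, hier, cfg, variant="full", k=3, seed=1)
    assert len(rep.folds) == 3
    assert all(0 <= f.auc <= 1 and 0 <= f.aupr <= 1 for f in rep.folds)
    assert all(f.leaked_test_edges == 0 for f in rep.folds)
    assert rep.mean_auc > 0.5  # better than chance even at tiny scale


def test_no_dropedge_variant_equals_p0(small_cv_setup):
    fix, hier, cfg = small_cv_setup
    from dataclasses import replace

    rep_nd = run_cv(fix.assoc, hier, cfg, variant="no_dropedge", k=3, seed=1)
    cfg_p0 = replace(cfg, train=replace(cfg.train, drop_rate=0.0))
    rep_p0 = run_cv(fix.assoc, hier, cfg_p0, variant="full", k=3, seed=1)
    for a, b in zip(rep_nd.folds, rep_p0.folds):
        assert a.auc == b.auc and a.aupr == b.aupr  # definitional equivalence


def test_scorer_plugin_interface(small_cv_setup):
    fix, hier, cfg = small_cv_setup
    # a trivial external scorer: the true planted propensity
    rep = run_cv(
        fix.assoc, hier, cfg, variant="full", k=3, seed=1,
        scorer=lambda masked, ctx: fix.propensity,
    )
    assert rep.mean_auc > 0.9  # the oracle scorer nails the planted labels


def test_report_roundtrip(small_cv_setup, tmp_path):
    fix, hier, cfg = small_cv_setup
    rep = run_cv(fix.assoc, hier, cfg, variant="mean_fusion", k=3, seed=1)
    p = tmp_path / "rep.json"
    rep.save(p)
    back = MetricsReport.load(p)
    assert back.to_dict() == rep.to_dict()


def test_unknown_variant_rejected(small_cv_setup):
    fix, hier, cfg = small_cv_setup
    with pytest.raises(ValueError, match="variant"):
        run_cv(fix.assoc, hier, cfg, variant="bogus", k=3)
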