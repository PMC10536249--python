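"""Heterogeneous graph, DropEdge, propagation operator, JK aggregation,
decoding, and training behavior."""

import numpy as np
import pytest

from midra.assoc import AssociationMatrix
from midra.gcn import (
    TrainConfig,
    build_hetero_graph,
    decode_scores,
    drop_edges,
    gcn_forward,
    init_weights,
    jk_aggregate,
    normalize_adjacency,
    train,
)
from midra.matrixio import SimilarityMatrix


def toy_graph(n_m=3, n_d=2, seed=0, topk=10):
    rng = np.random.default_rng(seed)
    mm = rng.random((n_m, n_m))
    mm = (mm + mm.T) / 2
    np.fill_diagonal(mm, 1.0)
    dd = rng.random((n_d, n_d))
    dd = (dd + dd.T) / 2
    np.fill_diagonal(dd, 1.0)
    A = (rng.random((n_m, n_d)) < 0.5).astype(float)
    if A.sum() == 0:
        A[0, 0] = 1.0
    am = AssociationMatrix(A, [f"m{i}" for i in range(n_m)], [f"d{j}" for j in range(n_d)])
    MM = SimilarityMatrix(mm, am.mirna_names, "MM")
    DD = SimilarityMatrix(dd, am.disease_names, "DD")
    cfg = TrainConfig(sim_topk=topk, seed=seed)
    return build_hetero_graph(MM, DD, am, cfg), am


def test_graph_block_structure():
    g, am = toy_graph()
    assert g.n == 5 and g.W.shape == (5, 5) and g.X.shape == (5, 5)
    assert np.allclose(g.W, g.W.T)
    assert np.all(np.diag(g.W) == 0)
    # cross block equals A
    assert np.array_equal(g.W[:3, 3:], am.A)
    # features are the block matrix rows
    assert np.array_equal(g.X[:3, 3:], am.A)


def test_graph_no_cross_edges_when_A_zero():
    mm = np.eye(3)
    dd = np.eye(2)
    am = AssociationMatrix(np.zeros((3, 2)), ["m0", "m1", "m2"], ["d0", "d1"])
    g = build_hetero_graph(
        SimilarityMatrix(mm, am.mirna_names), SimilarityMatrix(dd, am.disease_names), am
    )
    assert np.all(g.W[:3, 3:] == 0)


def test_dropedge_p0_identity_and_extremes():
    g, _ = toy_graph(10, 8, seed=1)
    rng = np.random.default_rng(0)
    g0 = drop_edges(g, 0.0, rng)
    assert np.array_equal(g0.W, g.W)
    g99 = drop_edges(g, 0.999, np.random.default_rng(0))
    assert g99.edge_count() <= g.edge_count() * 0.2
    with pytest.raises(ValueError):
        drop_edges(g, 1.0, rng)


def test_dropedge_removal_count_binomial():
    # a dense similarity fixture with many edges; removal count at p=0.4
    # must sit within 3 sigma of Binomial(n_edges, 0.4)
    g, _ = toy_graph(60, 50, seed=2, topk=30)
    n_edges = g.edge_count()
    assert n_edges > 1000
    p = 0.4
    rng = np.random.default_rng(123)
    removed = [n_edges - drop_edges(g, p, rng).edge_count() for _ in range(30)]
    mu = n_edges * p
    sigma = np.sqrt(n_edges * p * (1 - p))
    assert abs(np.mean(removed) - mu) < 3 * sigma / np.sqrt(len(removed))
    for r in removed:
        assert abs(r - mu) < 5 * sigma  # no single wild draw


def test_dropedge_symmetry():
    g, _ = toy_graph(10, 8, seed=3)
    gd = drop_edges(g, 0.5, np.random.default_rng(5))
    assert np.array_equal(gd.W, gd.W.T)


def test_normalize_adjacency():
    assert np.array_equal(normalize_adjacency(np.zeros((4, 4))), np.eye(4))
    W = np.array([[0.0, 1.0], [1.0, 0.0]])
    Ahat = normalize_adjacency(W)
    assert Ahat[0, 1] == pytest.approx(0.5)  # D = 2I with self-loops
    rng = np.random.default_rng(4)
    for _ in range(5):
        S = rng.random((12, 12))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0.0)
        ev = np.linalg.eigvalsh(normalize_adjacency(S))
        assert np.abs(ev).max() <= 1 + 1e-8


def test_forward_identity_on_edgeless_graph():
    # edgeless graph + identity weights + linear activation: output == input
    n = 6
    X = np.random.default_rng(0).random((n, n))
    Ahat = normalize_adjacency(np.zeros((n, n)))
    Ws = [np.eye(n)]
    bs = [np.zeros(n)]
    Hs, _, _ = gcn_forward(Ahat, X, Ws, bs, activation="identity")
    assert np.allclose(Hs[0], X)


def test_forward_permutation_equivariance():
    g, _ = toy_graph(5, 4, seed=6)
    rng = np.random.default_rng(1)
    Ws, bs = init_weights(g.n, (8, 8), rng)
    Ahat = normalize_adjacency(g.W)
    Hs, _, _ = gcn_forward(Ahat, g.X, Ws, bs)
    perm = np.random.default_rng(2).permutation(g.n)
    P = np.eye(g.n)[perm]
    # permute nodes AND the feature axis (features are the adjacency rows)
    Ahat_p = P @ Ahat @ P.T
    X_p = P @ g.X @ P.T
    Ws_p = [P @ Ws[0]] + Ws[1:]
    Hs_p, _, _ = gcn_forward(Ahat_p, X_p, Ws_p, bs)
    for H, Hp in zip(Hs, Hs_p):
        assert np.allclose(Hp, P @ H, atol=1e-10)


def test_jk_aggregate_modes():
    rng = np.random.default_rng(0)
    layers = [rng.random((4, 16)) for _ in range(3)]
    assert np.array_equal(jk_aggregate([layers[0]]), layers[0])
    cat = jk_aggregate(layers, "concat")
    assert cat.shape == (4, 48)
    dominated = [layers[0], layers[0] + 1.0]
    assert np.allclose(jk_aggregate(dominated, "max"), layers[0] + 1.0)
    with pytest.raises(ValueError):
        jk_aggregate([np.ones((4, 8)), np.ones((4, 16))], "max")


def test_decode_scores():
    Z = np.zeros((5, 4))
    Z[0] = [1, 0, 0, 0]
    Z[3] = [0, 1, 0, 0]  # orthogonal to node 0
    Z[4] = [1, 0, 0, 0]  # aligned with node 0, dot = 1
    s = decode_scores(Z, 3, 2)
    assert s.shape == (3, 2)
    assert s[0, 0] == pytest.approx(0.5)  # logistic(0)
    assert s[0, 1] == pytest.approx(1 / (1 + np.exp(-1)))
    assert ((s > 0) & (s < 1)).all()


def test_train_reduces_loss_and_is_deterministic(assoc_fixture, ssd, hierarchy):
    from midra.config import RunConfig
    from midra.evaluation import fold_similarities

    cfgr = RunConfig()
    mm, dd = fold_similarities(assoc_fixture.assoc, ssd, cfgr, "full")
    tc = TrainConfig(epochs=80, seed=11)
    g = build_hetero_graph(mm, dd, assoc_fixture.assoc, tc)
    r1 = train(g, tc)
    assert r1.loss_trace[-1] < r1.loss_trace[0]
    assert ((r1.scores > 0) & (r1.scores < 1)).all()
    r2 = train(g, tc)
    assert r1.loss_trace == r2.loss_trace
    assert np.array_equal(r1.scores, r2.scores)  # bitwise reproducible


def test_train_rejects_empty_positives():
    am = AssociationMatrix(np.zeros((3, 2)), ["m0", "m1", "m2"], ["d0", "d1"])
    g = build_hetero_graph(
        SimilarityMatrix(np.eye(3), am.mirna_names),
        SimilarityMatrix(np.eye(2), am.disease_names),
        am,
    )
    with pytest.raises(ValueError, match="positives"):
        train(g, TrainConfig(epochs=1))


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(drop_rate=1.0)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(jk_mode="lstm")
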