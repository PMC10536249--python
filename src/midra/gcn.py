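"""Heterogeneous graph construction and the DropEdge / jumping-knowledge GCN.

The prediction graph has n = n_m + n_d nodes (miRNAs first) and three edge
blocks: miRNA-miRNA edges from the fused similarity MM, disease-disease
edges from DD (each node keeps its top-k similarity neighbors, weights
kept), and miRNA-disease edges from the training-visible association matrix
(weight 1). Node features are the rows of the dense block matrix
[[MM, A], [A.T, DD]].

Training is full-graph. Each epoch:

1. DropEdge: every undirected edge is independently removed with
   probability p (both directions; self-loops are never dropped), and the
   symmetric normalization D^{-1/2}(W + I)D^{-1/2} is recomputed on the
   surviving edges.
2. Forward: L layers of propagate -> linear -> ReLU, keeping every layer's
   embeddings. The jumping-knowledge aggregate concatenates (or
   element-wise maxes) all layer embeddings; the plain-GCN ablation keeps
   only the last layer.
3. Decode: score(m_i, d_j) = logistic(z_i . z_j + b), b a learned scalar.
4. Loss: binary cross-entropy on the training positives versus an equal
   number of freshly sampled unknown pairs; Adam update.

Everything is plain numpy with hand-written gradients, so a fixed seed gives
bit-identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assoc import AssociationMatrix
from .matrixio import SimilarityMatrix

__all__ = [
    "TrainConfig",
    "HeteroGraph",
    "build_hetero_graph",
    "drop_edges",
    "normalize_adjacency",
    "init_weights",
    "gcn_forward",
    "jk_aggregate",
    "decode_scores",
    "train",
    "TrainResult",
]


@dataclass
class TrainConfig:
    """Hyper-parameters of the graph model.

    drop_rate: DropEdge deletion probability p in [0, 1).
    epochs: number of full-graph training epochs.
    layer_sizes: widths of the GCN layers (>= 1 layer).
    lr: Adam learning rate.
    neg_ratio: sampled negatives per positive each epoch.
    jk_mode: 'concat' | 'max' | 'none' ('none' = plain last-layer GCN).
    sim_topk: per-node neighbor count when sparsifying MM/DD into edges.
    drop_blocks: which edge blocks DropEdge touches
        ('both' | 'similarity' | 'association').
    activation: 'relu' | 'identity' (identity is for analytic checks).
    seed: rng seed; fixed seed => fully reproducible run.
    """

    drop_rate: float = 0.4
    epochs: int = 1000
    layer_sizes: tuple[int, ...] = (64, 64, 64)
    lr: float = 5e-3
    neg_ratio: float = 1.0
    jk_mode: str = "concat"
    sim_topk: int = 10
    drop_blocks: str = "both"
    activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.drop_rate < 1:
            raise ValueError("drop_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.jk_mode not in ("concat", "max", "none"):
            raise ValueError(f"unknown jk_mode {self.jk_mode!r}")
        if self.drop_blocks not in ("both", "similarity", "association"):
            raise ValueError(f"unknown drop_blocks {self.drop_blocks!r}")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class HeteroGraph:
    """Weighted undirected graph over n_m + n_d nodes, miRNAs first."""

    n_m: int
    n_d: int
    W: np.ndarray  # (n, n) symmetric, zero diagonal
    X: np.ndarray  # (n, n) node features: rows of [[MM, A], [A.T, DD]]
    mirna_names: list[str] = field(default_factory=list)
    disease_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.n_m + self.n_d

    def edge_count(self) -> int:
        """Number of undirected edges."""
        return int(np.count_nonzero(np.triu(self.W, k=1)))


def _topk_sparsify(S: np.ndarray, k: int) -> np.ndarray:
    """Keep each node's k strongest off-diagonal similarities, symmetric
    closure by union (weights kept)."""
    n = S.shape[0]
    k = min(k, n - 1)
    out = np.zeros_like(S)
    for i in range(n):
        row = S[i].copy()
        row[i] = -np.inf
        order = np.lexsort((np.arange(n), -row))
        nbrs = order[:k]
        nbrs = nbrs[S[i, nbrs] > 0]
        out[i, nbrs] = S[i, nbrs]
    return np.maximum(out, out.T)


def build_hetero_graph(
    MM: SimilarityMatrix,
    DD: SimilarityMatrix,
    A_train: AssociationMatrix,
    cfg: TrainConfig | None = None,
) -> HeteroGraph:
    """Assemble the heterogeneous graph from fused similarities and the
    training association matrix."""
    cfg = cfg or TrainConfig()
    n_m, n_d = A_train.n_m, A_train.n_d
    if MM.shape != (n_m, n_m) or DD.shape != (n_d, n_d):
        raise ValueError("similarity/association shapes are inconsistent")
    n = n_m + n_d
    W = np.zeros((n, n))
    W[:n_m, :n_m] = _topk_sparsify(MM.values, cfg.sim_topk)
    W[n_m:, n_m:] = _topk_sparsify(DD.values, cfg.sim_topk)
    W[:n_m, n_m:] = A_train.A
    W[n_m:, :n_m] = A_train.A.T
    np.fill_diagonal(W, 0.0)
    X = np.zeros((n, n))
    X[:n_m, :n_m] = MM.values
    X[n_m:, n_m:] = DD.values
    X[:n_m, n_m:] = A_train.A
    X[n_m:, :n_m] = A_train.A.T
    return HeteroGraph(n_m, n_d, W, X, list(A_train.mirna_names), list(A_train.disease_names))


def drop_edges(graph: HeteroGraph, p: float, rng: np.random.Generator) -> HeteroGraph:
    """Independently remove each undirected edge with probability p.

    Removal is symmetric; the choice of blocks is made by the caller via
    :func:`_block_mask`. p = 0 returns an identical edge set.
    """
    return _drop_edges_blocks(graph, p, rng, "both")


def _block_mask(graph: HeteroGraph, blocks: str) -> np.ndarray:
    """Boolean (n, n) mask of entries eligible for DropEdge."""
    n, n_m = graph.n, graph.n_m
    mask = np.zeros((n, n), dtype=bool)
    if blocks in ("both", "similarity"):
        mask[:n_m, :n_m] = True
        mask[n_m:, n_m:] = True
    if blocks in ("both", "association"):
        mask[:n_m, n_m:] = True
        mask[n_m:, :n_m] = True
    return mask


def _drop_edges_blocks(
    graph: HeteroGraph, p: float, rng: np.random.Generator, blocks: str
) -> HeteroGraph:
    if not 0 <= p < 1:
        raise ValueError("drop rate must be in [0, 1)")
    W = graph.W.copy()
    if p > 0:
        iu, ju = np.nonzero(np.triu(W, k=1))
        eligible = _block_mask(graph, blocks)[iu, ju]
        keep = np.ones(iu.size, dtype=bool)
        draws = rng.random(iu.size)  # one draw per edge, eligible or not
        keep[eligible] = draws[eligible] >= p
        drop = ~keep
        W[iu[drop], ju[drop]] = 0.0
        W[ju[drop], iu[drop]] = 0.0
    return HeteroGraph(graph.n_m, graph.n_d, W, graph.X, graph.mirna_names, graph.disease_names)


def normalize_adjacency(W: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation operator D^{-1/2}(W + I)D^{-1/2}.

    Self-loops guarantee every node (isolated ones included) has degree
    >= 1; the spectral radius is <= 1.
    """
    if (W < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    Wt = W + np.eye(W.shape[0])
    d = Wt.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return Wt * dinv[:, None] * dinv[None, :]


def init_weights(
    in_dim: int, layer_sizes: tuple[int, ...], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Glorot-uniform weights and zero biases for each layer."""
    Ws, bs = [], []
    d = in_dim
    for h in layer_sizes:
        lim = np.sqrt(6.0 / (d + h))
        Ws.append(rng.uniform(-lim, lim, size=(d, h)))
        bs.append(np.zeros(h))
        d = h
    return Ws, bs


def gcn_forward(
    Ahat: np.ndarray,
    X: np.ndarray,
    Ws: list[np.ndarray],
    bs: list[np.ndarray],
    activation: str = "relu",
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Run the GCN layers; returns (layer activations H_l, pre-activations
    Z_l, propagated inputs Ahat @ H_{l-1}) for backprop and JK aggregation.
    """
    H = X
    Hs, Zs, Ps = [], [], []
    for li, (W, b) in enumerate(zip(Ws, bs)):
        P = Ahat @ H
        Z = P @ W + b
        if not np.isfinite(Z).all():
            raise FloatingPointError(f"non-finite activation at layer {li}")
        H = np.maximum(Z, 0.0) if activation == "relu" else Z
        Ps.append(P)
        Zs.append(Z)
        Hs.append(H)
    return Hs, Zs, Ps


def jk_aggregate(layers: list[np.ndarray], mode: str = "concat") -> np.ndarray:
    """Jumping-knowledge aggregation of per-layer embeddings."""
    if not layers:
        raise ValueError("need at least one layer")
    if len(layers) == 1:
        return layers[0]
    if mode == "concat":
        return np.hstack(layers)
    if mode == "max":
        widths = {h.shape[1] for h in layers}
        if len(widths) != 1:
            raise ValueError("max-mode JK requires equal layer widths")
        return np.maximum.reduce(layers)
    if mode == "none":
        return layers[-1]
    raise ValueError(f"unknown JK mode {mode!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode_scores(Z: np.ndarray, n_m: int, n_d: int, bias: float = 0.0) -> np.ndarray:
    """Inner-product decoder: logistic(z_m . z_d + bias) for every pair.

    The scalar bias is learned alongside the GCN weights; with ReLU
    embeddings every inner product is non-negative, so without it no score
    could fall below 0.5 and the fixed-threshold metrics would degenerate.
    """
    logits = Z[:n_m] @ Z[n_m : n_m + n_d].T + bias
    return _sigmoid(logits)


@dataclass
class TrainResult:
    Ws: list[np.ndarray]
    bs: list[np.ndarray]
    scores: np.ndarray  # (n_m, n_d) probabilities from the un-dropped graph
    loss_trace: list[float]
    decoder_bias: float = 0.0


def _sample_negatives(
    A: np.ndarray, count: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``count`` unknown (zero) pairs uniformly without replacement."""
    zi, zj = np.nonzero(A == 0)
    if zi.size == 0:
        raise ValueError("no unknown pairs to sample negatives from")
    count = min(count, zi.size)
    pick = rng.choice(zi.size, size=count, replace=False)
    return zi[pick], zj[pick]


def train(graph: HeteroGraph, cfg: TrainConfig) -> TrainResult:
    """Train the model end-to-end; deterministic under cfg.seed.

    Raises FloatingPointError if the loss diverges to a non-finite value.
    """
    rng = np.random.default_rng(cfg.seed)
    n_m, n_d = graph.n_m, graph.n_d
    A = graph.W[:n_m, n_m:]
    pos_i, pos_j = np.nonzero(A > 0)
    if pos_i.size == 0:
        raise ValueError("no training positives")

    Ws, bs = init_weights(graph.X.shape[1], cfg.layer_sizes, rng)
    # Adam state
    mW = [np.zeros_like(w) for w in Ws]
    vW = [np.zeros_like(w) for w in Ws]
    mb = [np.zeros_like(b) for b in bs]
    vb = [np.zeros_like(b) for b in bs]
    b0, mb0, vb0 = 0.0, 0.0, 0.0  # scalar decoder bias
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    L = len(Ws)
    widths = cfg.layer_sizes
    loss_trace: list[float] = []

    for epoch in range(1, cfg.epochs + 1):
        g = _drop_edges_blocks(graph, cfg.drop_rate, rng, cfg.drop_blocks)
        Ahat = normalize_adjacency(g.W)
        neg_count = max(1, int(round(cfg.neg_ratio * pos_i.size)))
        ni, nj = _sample_negatives(A, neg_count, rng)
        pi = np.concatenate([pos_i, ni])
        pj = np.concatenate([pos_j, nj]) + n_m  # disease node ids
        y = np.concatenate([np.ones(pos_i.size), np.zeros(ni.size)])

        Hs, Zs, Ps = gcn_forward(Ahat, graph.X, Ws, bs, cfg.activation)
        Zrep = jk_aggregate(Hs, cfg.jk_mode) if cfg.jk_mode != "none" else Hs[-1]

        logits = np.einsum("ij,ij->i", Zrep[pi], Zrep[pj]) + b0
        prob = _sigmoid(logits)
        loss = -np.mean(y * np.log(prob + 1e-12) + (1 - y) * np.log(1 - prob + 1e-12))
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss diverged at epoch {epoch}")
        loss_trace.append(float(loss))

        # --- backward ---
        gl = (prob - y) / y.size  # dL/dlogit
        db0 = float(gl.sum())
        dZrep = np.zeros_like(Zrep)
        np.add.at(dZrep, pi, gl[:, None] * Zrep[pj])
        np.add.at(dZrep, pj, gl[:, None] * Zrep[pi])

        # split JK gradient into per-layer shares
        dH_jk: list[np.ndarray] = [np.zeros_like(h) for h in Hs]
        if cfg.jk_mode == "concat" and L > 1:
            off = 0
            for li, w in enumerate(widths):
                dH_jk[li] = dZrep[:, off : off + w]
                off += w
        elif cfg.jk_mode == "max" and L > 1:
            stack = np.stack(Hs)  # (L, n, w)
            winner = stack.argmax(axis=0)
            for li in range(L):
                dH_jk[li] = dZrep * (winner == li)
        else:  # single layer or plain GCN
            dH_jk[-1] = dZrep

        dWs = [np.zeros_like(w) for w in Ws]
        dbs = [np.zeros_like(b) for b in bs]
        dH_next = np.zeros_like(Hs[-1])
        for li in range(L - 1, -1, -1):
            dH = dH_jk[li] + dH_next
            dZ = dH * (Zs[li] > 0) if cfg.activation == "relu" else dH
            dWs[li] = Ps[li].T @ dZ
            dbs[li] = dZ.sum(axis=0)
            if li > 0:
                dH_next = Ahat.T @ (dZ @ Ws[li].T)

        # --- Adam update ---
        for li in range(L):
            for param, grad, m, v in (
                (Ws[li], dWs[li], mW, vW),
                (bs[li], dbs[li], mb, vb),
            ):
                m[li] = beta1 * m[li] + (1 - beta1) * grad
                v[li] = beta2 * v[li] + (1 - beta2) * grad**2
                mhat = m[li] / (1 - beta1**epoch)
                vhat = v[li] / (1 - beta2**epoch)
                param -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
        mb0 = beta1 * mb0 + (1 - beta1) * db0
        vb0 = beta2 * vb0 + (1 - beta2) * db0**2
        b0 -= cfg.lr * (mb0 / (1 - beta1**epoch)) / (np.sqrt(vb0 / (1 - beta2**epoch)) + eps)

    # final scores on the full (un-dropped) graph
    Ahat = normalize_adjacency(graph.W)
    Hs, _, _ = gcn_forward(Ahat, graph.X, Ws, bs, cfg.activation)
    Zrep = jk_aggregate(Hs, cfg.jk_mode) if cfg.jk_mode != "none" else Hs[-1]
    scores = decode_scores(Zrep, n_m, n_d, bias=b0)
    return TrainResult(Ws=Ws, bs=bs, scores=scores, loss_trace=loss_trace, decoder_bias=float(b0))
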