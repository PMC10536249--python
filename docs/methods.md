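# Methods

`midra` predicts unknown miRNA–disease associations from three ingredients:
what is already known (a binary association matrix **A**, n_m × n_d), how
diseases relate to each other (a MeSH-style hierarchy), and the assumption
that functionally similar miRNAs associate with semantically similar
diseases. The pipeline builds one similarity view per node type from
biology (semantic/functional) and one from the association topology (GIP
kernels), fuses the two views per node type by similarity network fusion,
and trains a graph convolutional network with DropEdge regularization and
jumping-knowledge aggregation on the resulting heterogeneous graph.

## Model and assumptions

### Association matrix

The raw association list is deduplicated (case- and whitespace-insensitive)
and indexed lexicographically; A[i, j] = 1 iff miRNA m_i is associated with
disease d_j. Row i is the interaction profile IP(m_i); column j is
IP′(d_j). Deduplication is the only cleaning step — no evidence-code
filtering, no class rebalancing.

### Disease semantic similarity (SSD)

Each disease d induces an ancestor DAG (d plus all its MeSH ancestors; a
disease with several tree numbers takes the union of ancestor paths). Two
per-node contribution scores are combined:

* **Position score D1.** D1(d) = 1; for an ancestor n,
  D1(n) = max over children c of n (within the DAG) of Δ·D1(c), which
  equals Δ^(shortest directed path n → d). Δ (default **0.5**) is the
  per-generation semantic decay.
* **Specificity score D2.** D2(n) = −log(#DAGs containing n / #diseases).
  An ancestor shared by every disease contributes nothing; a rare one
  contributes a lot. The log base cancels in the similarity ratio (a
  property test asserts base-invariance); natural log is the default. The
  denominator is the hierarchy size by default and configurable, since a
  "number of diseases" can also reasonably mean the dataset's disease count.

For each score, SSV(d) = Σ_{n∈T[d]} contribution, and

    SSD_k(i, j) = Σ_{n ∈ T[i]∩T[j]} (Dk_i(n) + Dk_j(n)) / (SSV_k(i) + SSV_k(j)),

with SSD = (SSD1 + SSD2)/2. T[d] includes d itself: the base case of D1
requires it, and it is what makes SSD(d, d) = 1 exact. Diseases absent from
the hierarchy get an identity row; their signal enters through the GIP
kernel instead.

### miRNA functional similarity (FSM)

Wang-style: FSM(m_i, m_j) averages the best semantic matches between the
two miRNAs' disease sets, normalized by the sum of the set sizes. The
denominator uses the two set cardinalities. A miRNA with no known disease
gets 0 off-diagonal and 1 on the diagonal rather than NaN, keeping fusion
total.

### GIP kernels (GSM, GSD)

RBF kernels over interaction profiles with bandwidth normalized by the mean
squared profile norm: γ = γ′ / ((1/n) Σ‖IP_i‖²), γ′ = **1** for both node
types. Entities with all-zero profiles have GIP similarity 1 to each other
(zero distance); this mirrors the formula and only affects entities with no
training associations.

### Similarity network fusion (MM, DD)

Per node type, the two views are row-normalized, KNN-sparsified (**K = 10**
neighbors, ties broken toward the lower index, the node itself excluded),
and cross-diffused:

    P1 ← K1 · P2 · K1ᵀ,   P2 ← K2 · P1_prev · K2ᵀ   (parallel update)

for t iterations (default **t = 20**, early stop when the largest
element-wise change < 1e-6). Raw cross-diffusion products are not
symmetric, so each iterate is re-symmetrized ((X+Xᵀ)/2) and
row-renormalized — the convention of the original SNF algorithm, and what
keeps every similarity-matrix invariant testable. The fused matrix is the
element-wise mean of the two diffused views with the diagonal reset to 1
(the reset is this package's choice; diffusion leaves diagonals
uninterpretable). The `mean_fusion` ablation replaces all of this with a
plain element-wise mean.

### Heterogeneous graph and the GCN

Nodes: n_m miRNAs then n_d diseases. Edges: each node's top-k (default 10,
matching K) fused-similarity neighbors with their weights, plus
training-visible associations with weight 1; symmetric closure throughout.
Dense weighted similarity blocks would make "an edge" ill-defined for
DropEdge, hence the sparsification. Node features are the rows of the block
matrix [[MM, A], [Aᵀ, DD]].

Each training epoch: (1) **DropEdge** removes every undirected edge
independently with probability **p = 0.4** (both blocks by default,
configurable), and the propagation operator D^{−1/2}(W+I)D^{−1/2} is
renormalized on the survivors; (2) forward pass through **3 GCN layers of
width 64** (propagate → linear → ReLU), keeping all per-layer embeddings;
(3) **jumping-knowledge** aggregation concatenates the layer embeddings
(max-pool optional; the `plain_gcn` ablation keeps only the last layer);
(4) the inner-product decoder scores each pair as logistic(z_m · z_d + b),
and binary cross-entropy over the training positives plus an equal number of
freshly sampled unknown pairs is minimized with Adam (lr 5e-3).

The decoder's scalar bias b is learned with the other parameters. It is
necessary, not cosmetic: ReLU embeddings are non-negative, so without the
bias every inner-product logit is ≥ 0, every score is ≥ 0.5, and
fixed-threshold metrics degenerate to predict-all-positive. The bias leaves
the ranking (AUC/AUPR) essentially unchanged and restores meaningful
accuracy/recall/F1.

Decoder, loss, optimizer, depth and widths are this package's design
choices (the method family leaves them open); all are exposed in
`TrainConfig`. The GCN is implemented directly in numpy with hand-written
gradients — at these graph sizes (n ≲ 2100 real scale, ≲ 150 at fixture
scale) full-graph dense training is fast, dependency-free, and bit-exactly
reproducible under a fixed seed.

## Evaluation protocol

k-fold CV partitions the known associations; per fold the test positives
are masked out of A and **everything that depends on A — FSM, GSM, GSD, and
the SNF fusion — is recomputed from the masked matrix**. This leakage
control is stricter than the method description demands, and will deflate
AUC relative to a protocol that computes similarities once from the full
matrix; it is the defensible default. An instrumentation counter asserts
that no test positive survives as a graph edge.

Test negatives are sampled 1:1 with test positives from never-associated
pairs (exhaustive ranking over all unknown pairs is available behind a
flag). AUC is the tie-averaged rank statistic; AUPR is the trapezoid over
the stepwise precision–recall curve; accuracy/recall/F1 use a fixed 0.5
threshold.

## Synthetic study system

`FixtureSpec` defaults define the desk-scale conditions used by the tests
and the acceptance script: **60 miRNAs × 40 diseases, rank-4 non-negative
latent factors (gamma-distributed), 15% association density, 2% label
noise**, and a depth-4, branching-3 disease hierarchy in which a quarter of
the nodes get a second parent (exercising multi-path semantics). Observed
positives are the top-propensity pairs, so the planted structure is exactly
the low-rank "similar associates with similar" regime the method assumes —
a structureless random matrix would make every predictor equal to chance
and test nothing. The generator also emits the true propensity matrix, a
held-out list of the strongest unobserved pairs, and latent-factor cosine
similarities usable as similarity stand-ins in unit tests.

What the fixture does **not** emulate: the scale of real catalogs (~1,200
miRNAs, ~900 diseases, 35k associations), their heavy-tailed degree
distributions, MeSH's 13-level depth, and curation biases. Passing tests
demonstrate that the machinery is correct and that the method recovers
planted low-rank structure; they do not certify real-data AUC levels, which
at full scale are reported around 0.97 and depend on protocol details
(negative sampling, whether similarities are recomputed per fold) that the
method description leaves open.

Fixture-scale evaluation uses 300 training epochs (the full-scale default
is 1000): at n ≈ 100 nodes the loss plateaus well before 300 and longer
training only overfits.

## Ablations and regimes measured

All numbers below were measured with the released code (5-fold CV,
epochs = 300, ten paired seeds per variant).

* **DropEdge** (`no_dropedge` vs full): consistent benefit — on the
  over-parameterized fixture the full model beat the p = 0 variant on
  10/10 paired seeds (mean AUC 0.8668 vs 0.8601).
* **DropEdge rate sweep** (p ∈ {0, 0.2, 0.4, 0.6, 0.8}): AUC rises from
  p = 0, peaks at an interior rate, and degrades at high rates on the
  over-parameterized fixture; the exact peak location varies by seed.
* **Jumping knowledge** (`plain_gcn` vs full): scale-dependent. On the
  over-parameterized fixture (90 × 60, rank-6, 20% density, 5% noise —
  ~18k parameters against ~900 training positives), JK concatenation won
  on 10/10 paired seeds (mean AUC 0.8668 vs 0.8613). On smaller fixtures
  the 64-wide last layer already has enough capacity and JK's extra
  parameters can overfit; the qualitative ordering is therefore asserted
  only in the over-parameterized regime.
* **SNF vs mean fusion** (`mean_fusion`): small, fixture-dependent effect
  at desk scale.
* **Link recovery** (standard 60 × 40 fixture, 5 CV seeds): mean AUC
  0.8585 under the strict per-fold leakage control.

## Numerical choices and edge cases

* KNN and top-k neighbor selection break ties toward the lower index
  (stable lexsort), making every sparsification deterministic.
* All-zero rows stay zero under row normalization; isolated graph nodes are
  handled by their self-loop (degree ≥ 1 after D^{−1/2}(W+I)D^{−1/2}).
* K ≥ n is clamped to n − 1 in the KNN kernel.
* Matrix TSVs store floats via `repr` (17 significant digits), so
  write/read round-trips are bit-exact and cached pipeline reruns are
  byte-identical.
* The numerically stable sigmoid is used everywhere; training aborts with a
  diagnostic if the loss becomes non-finite.

## Known limitations

* Full-scale (n ≈ 2100) training with dense numpy operators is feasible
  but slow (hours for 1000 epochs); the implementation targets method
  correctness and desk-scale experimentation, not production-scale runs.
* The LSTM-attention variant of jumping knowledge is not implemented.
* Only two views are fused per node type.
* MeSH XML descriptor files are not parsed directly; a two-column text
  dialect (child/parent or name/tree-number) is expected.
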