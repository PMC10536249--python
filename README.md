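# midra

**miRNA–disease association prediction** by similarity fusion and a
DropEdge-regularized, jumping-knowledge graph convolutional network.

Experimentally validating which miRNAs drive which diseases is slow and
expensive; computational ranking of candidate pairs lets curators and wet
labs prioritize. `midra` takes a curated association list (HMDD-style
two-column export) and a MeSH-style disease hierarchy and produces a score
in (0, 1) for every miRNA–disease pair.

## Method at a glance

1. **Association matrix** A ∈ {0,1}^(n_m×n_d), A[i,j] = 1 iff miRNA m_i is
   associated with disease d_j.
2. **Disease semantic similarity** SSD from per-disease MeSH ancestor DAGs:
   the mean of a position-based score (contribution Δ^path-length, Δ = 0.5)
   and a specificity-based score (−log DAG frequency).
3. **miRNA functional similarity** FSM: best-match semantic similarity
   between the two miRNAs' disease sets (Wang measure).
4. **GIP kernels** GSM/GSD: RBF kernels over rows/columns of A with
   bandwidth γ = γ′/mean‖IP‖², γ′ = 1.
5. **Similarity network fusion**: {FSM, GSM} → MM and {SSD, GSD} → DD by
   row normalization, K = 10 nearest-neighbor sparsification, and iterative
   cross-diffusion.
6. **Prediction**: a heterogeneous graph over n_m + n_d nodes (similarity
   edges + association edges) is trained with per-epoch **DropEdge**
   (p = 0.4) through a 3-layer GCN whose **jumping-knowledge** head
   concatenates all layer embeddings; an inner-product decoder gives
   score(m_i, d_j) = σ(z_i · z_j + b) with a learned scalar bias b.

Evaluation is k-fold cross-validation with strict leakage control (all
A-derived similarities recomputed from the fold-masked matrix), ROC
AUC/AUPR, a DropEdge-rate sweep, and three ablations (mean fusion instead
of SNF, no DropEdge, plain last-layer GCN). See `docs/methods.md` for the
full model description and design rationale.

## Worked example

Everything runs on synthetic data generated by the package itself:

```bash
midra make-fixture --kind all --seed 7 --out demo/
cat > demo/config.json <<'EOF'
{
  "assoc_path": "demo/associations.tsv",
  "hierarchy_path": "demo/hierarchy.tsv",
  "out_dir": "demo/run",
  "semantic": {"delta": 0.5, "log_base": 2.718281828459045, "universe": null},
  "gip": {"gamma_prime_m": 1.0, "gamma_prime_d": 1.0},
  "snf_k": 10, "snf_t": 20,
  "train": {"drop_rate": 0.4, "epochs": 300, "layer_sizes": [64, 64, 64],
            "lr": 0.005, "neg_ratio": 1.0, "jk_mode": "concat",
            "sim_topk": 10, "drop_blocks": "both", "activation": "relu",
            "seed": 7}
}
EOF
midra run --config demo/config.json
midra cv --config demo/config.json --k 5 --report demo/report
```

The `run` command prints the stages it recomputed and caches seven
intermediate matrices (A, SSD, FSM, GSM, GSD, MM, DD) plus `scores.tsv` in
`demo/run/`:

```
{"out_dir": "demo/run", "recomputed": ["A", "DD", "FSM", "GSD", "GSM", "MM", "SSD", "scores"]}
```

The `cv` command prints the cross-validated metrics, e.g.

```
full 5-fold: AUC=0.8532 AUPR=0.8784 acc=0.7644 recall=0.5867 F1=0.7129
```

meaning: over 5 folds, a held-out true association outranks a sampled
unknown pair 85.3% of the time (AUC), the precision–recall area is 0.878,
and at the 0.5 score threshold 76% of test pairs are classified correctly.
Rerunning `midra run` with the same config reuses every cache and
reproduces `scores.tsv` byte-for-byte.

The same machinery is available as a library:

```python
from midra import FixtureSpec, RunConfig, TrainConfig, run_cv
from midra.fixtures import generate_associations, generate_hierarchy

spec = FixtureSpec(seed=7)
fix, hier = generate_associations(spec), generate_hierarchy(spec)
cfg = RunConfig(train=TrainConfig(epochs=300, seed=7))
report = run_cv(fix.assoc, hier, cfg, variant="full", k=5, seed=7)
print(report.mean_auc, report.mean_aupr)
```

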