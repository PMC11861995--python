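# connectogcn

Graph convolutional networks for **sex classification on structural brain
connectomes**, built to study three questions that matter for pediatric
neuroimaging: whether a small pediatric cohort can be *enriched* with a
larger adult cohort at training time (a few-shot-style transfer strategy),
how architectural choices (depth, pooling/aggregation, skip connections)
shape what a connectome GNN can learn, and how sensitive the resulting
models are to white-box adversarial perturbations.

It is a library for researchers in network neuroscience and
machine-learning-for-neuroimaging who want a tested, reproducible pipeline
rather than a one-off script: every stage — synthetic cohort generation,
graph kernels, five classifiers, cross-validated training regimes, the FGSM
attack — is importable, seeded, and covered by oracle-backed tests. Because
clinical connectome cohorts are typically access-restricted, the package
ships a synthetic generator that plants a configurable sex effect and a
cohort-level protocol shift into streamline-density-like weighted graphs,
so every downstream claim is verifiable end to end.

## The model

A subject is a weighted graph over a brain parcellation: adjacency
`A ∈ R^{n×n}` (symmetric, non-negative, zero diagonal; n = 379 regions for
a whole-brain parcellation), node features `X` (default: the connectivity
profile, `X = A`), and a binary label (female = 1). A GCN layer propagates
node embeddings through the symmetrically normalized adjacency

    H_l = σ( A* H_{l-1} W_l + b_l ),   H_0 = X,   A* = D̃^{-1/2} (A + I) D̃^{-1/2}

Five classifiers are built from this kernel and standard learners:

| model | architecture | trainable parameters (n = 379) |
|---|---|---|
| `gcn_simple` | ReLU GCN layers [64, 64] → global mean pool → sigmoid head | 28,545 |
| `gcn_residual` | tanh GCN layers [32, 32, 32]; per-layer mean-aggregation summaries concatenated at the readout (skip connections) | 14,369 |
| `mlp` | flattened `X` (379² inputs) → 512 → 256 → 128 → 1, ReLU + dropout | 73,709,057 (7.37 × 10⁷) |
| `rf` / `svm` | flattened `X` → PCA(100) → random forest / rbf SVM (Platt-calibrated) | — |

Deep models train with Adam (lr 1e-3, weight decay 5e-4) under weighted
binary cross entropy, 50% dropout, and early stopping on validation loss
(patience 35 within 100 epochs). Evaluation is 5-fold cross-validation
stratified by (label, cohort) — 70/10/20 train/validation/test for deep
models, 80/20 for RF/SVM — reporting accuracy and AUC as mean ± sample SD
over folds, overall and per cohort stratum. Four regimes are provided:
adult→adult, pediatric→pediatric, adult→pediatric external validation, and
the pooled *enriched* regime with cohort-stratified splits. Adversarial
sensitivity uses the fast gradient sign method,
`X_adv = X + ε·sign(∇_X L)`, swept over ε ∈ {0} ∪ [1e-5, 1e-3], each CV
fold attacked white-box by its own model. The backpropagation engine is
hand-written numpy (verified against finite differences), so runs are
bit-reproducible from their seeds.

## Worked example

`examples/02_training_regimes.py` trains the simple GCN and a
random-forest baseline on the standard synthetic benchmark (60 regions,
250 adult + 50 pediatric subjects, multiplicative sex effect 0.3 on 10% of
edges) under pediatric-only and adult-enriched regimes:

```
pediatric_pediatric (pediatric test subjects):
  gcn_simple: accuracy  58.0 ±  4.5 %   AUC 0.65
          rf: accuracy  64.0 ± 13.4 %   AUC 0.63

enriched (pediatric test subjects):
  gcn_simple: accuracy  74.0 ±  5.5 %   AUC 0.74
          rf: accuracy  68.0 ±  8.4 %   AUC 0.88
```

Accuracies are mean ± sample SD over the five cross-validation folds of
pediatric test subjects. Pediatric-only training (40 training subjects per
fold) leaves the GCN near chance; pooling the adult cohort into training
lifts its pediatric accuracy by 16 points — the data-enrichment effect the
pipeline is designed to measure. The other example scripts generate and
round-trip datasets (`01`), ablate the residual model's skip connections
(`03`), and trace the FGSM accuracy curve (`04`).

A thin CLI wraps the same machinery for shell use:

```sh
connectogcn generate --config gen.yaml --seed 3 --out data/
connectogcn run      --config study.yaml --seed 5 --out study_out/
connectogcn explore  --config study.yaml --out study_out/   # depth / pooling / skips
connectogcn attack   --config study.yaml --out study_out/   # FGSM sweep
connectogcn report   --out study_out/
```

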