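# Methods

`connectogcn` studies how graph convolutional networks classify sex from
structural brain connectomes, with particular attention to a small pediatric
cohort that can be *enriched* with a larger adult cohort during training, to
architecture choices (depth, pooling/aggregation, skip connections), and to
white-box adversarial sensitivity. Because real clinical connectome cohorts
are access-restricted, the package pairs the modeling pipeline with a
synthetic generator whose planted effects make every claim testable end to
end.

## Data model

A subject is a weighted structural connectivity graph over a fixed brain
parcellation: a symmetric, non-negative, zero-diagonal adjacency `A` (one
row/column per region; 379 regions for a whole-brain multi-modal
parcellation, freely smaller in tests), a node feature matrix `X`, a binary
sex label (female = 1, fixing the positive class for AUC), and a cohort tag
(`adult` / `pediatric`). Node features default to the *connectivity
profile* `X = A` — each region is described by its full row of connection
weights — with weighted degree and one-hot indicator schemes as
alternatives. The profile default keeps the adversarial attack on "the node
feature matrix" meaningful and matches common practice in connectome GNNs.

## Synthetic cohorts

Edge weights are log-additive and exponentiated:

    W_ij = exp( B_ij + shift·1[pediatric] + beta·M_ij·1[female] + e_ij )

* `B` — dataset-level base structure: a block (community) log-boost of 1.0
  over a background of −1.0, plus frozen edge-level heterogeneity
  (SD 0.5). Exponentiation yields non-negative, heavy-tailed weights like
  streamline densities.
* `M` — a symmetric 0/1 mask drawn once per dataset over a fraction
  (default 10%) of off-diagonal edges. Sharing `M` across subjects is what
  makes the sex difference learnable rather than noise.
* `beta` — the log-scale sex effect; affected female edges are multiplied
  by `exp(beta)`.
* `shift` — a log-scale offset applied to every pediatric edge,
  emulating protocol/age differences between cohorts; it acts on both sexes
  equally, so within-cohort female/male weight ratios are invariant to it.
* `e_ij` — i.i.d. symmetric Gaussian subject noise.

Female counts are the rounded target fractions (defaults 53.4% adult,
56.3% pediatric), and identical config + seed reproduces the dataset
bit for bit.

The **standard benchmark** used by the test battery and the acceptance
script is the scaled-down condition `n_regions = 60`, `n_adult = 250`,
`n_pediatric = 50`, `beta = 0.3`, 10% affected edges, `noise_sd = 0.5`,
`shift = 0.4`, 5 blocks. The effect is deliberately subtle — a ~35%
multiplicative difference on a minority of edges under comparable
between-subject noise — so cross-validated accuracies land in the 60–85%
band where training-set size and architecture choices matter, rather than at
ceiling. Null-calibration runs use `beta = 0` with *balanced* sex fractions,
since the 50% chance level that calibration is checked against presumes
balanced classes. What the generator does **not** emulate: spatial
autocorrelation of real parcellations, hub/rich-club topology,
age-continuous maturation within the pediatric cohort, site/scanner batch
structure beyond a single global shift, and any relationship between the
affected edge set and anatomy. Passing tests therefore certify the
machinery (learnability, transfer direction, attack mechanics), not
real-data effect sizes.

## Models

* **Simple GCN** — layers `H_l = ReLU(A* H_{l-1} W_l + b_l)` with widths
  [64, 64], global mean pooling to one graph vector, dropout 0.5, linear
  sigmoid head. `A* = D̃^{-1/2}(A+I)D̃^{-1/2}` is the symmetric
  normalization with self-loops; its spectrum lies in [−1, 1], and isolated
  nodes map to zero rows instead of dividing by zero.
* **Residual GCN** — tanh layers of width 32 (default three); after each
  layer a permutation-invariant aggregation summary (column mean, max as a
  variant) is emitted, and the readout concatenates the per-layer summaries
  (the skip connections). With skips ablated only the final layer's summary
  reaches the head. This realizes "intermediate graph embeddings feeding a
  joint readout" in the most ablation-friendly way; other readings of a
  residual readout exist, and published parameter counts for such models are
  not reproducible without the exact head dimensions, so the package
  documents its own counts (28,545 for the simple GCN and 14,369 for the
  residual model at 379 regions with profile features).
* **MLP** — the flattened feature matrix (379² = 143,641 inputs) through
  ReLU layers 512/256/128 with dropout, then a sigmoid head: 73,709,057
  trainable scalars (7.37 × 10⁷), the size that pins down the flattened
  full-matrix input convention.
* **RF / SVM baselines** — flattened features reduced by PCA to 100
  components (capped at the training-fold sample count), then a
  100-tree random forest or an rbf SVM; SVM scores come from Platt-style
  sigmoid calibration fit on the training folds. PCA lives inside the fold
  pipeline, so test folds are projected with frozen components.

The deep models are implemented directly in numpy with hand-derived
backpropagation, verified against central finite differences for every
parameter and for the input gradient (the FGSM ingredient). All arithmetic
is float64, making runs bit-reproducible from their seeds.

## Training and evaluation

Deep models train with Adam (learning rate 1e-3, weight decay 5e-4 folded
into the gradient, batch size 16) for up to 100 epochs under weighted binary
cross entropy, class weights being inverse training-split frequencies
normalized to mean 1. Early stopping monitors validation loss with
patience 35 and restores the best-validation weights; a strictly-lower
criterion means a validation curve flat from epoch 1 stops at epoch 36 with
the first epoch's weights. Batch size is a package choice (small cohorts);
the monitored quantity is validation loss because it is the curve the
training protocol plots.

Splits are 5-fold, stratified jointly by (label, cohort); each fold's 20% is
the test set. Deep models re-split the remaining 80% into 7:1
train:validation (70/10/20 overall); RF/SVM use the 80% whole. Strata
smaller than five subjects trigger a warning and best-effort fallback
(label-only, then unstratified). A leakage audit asserting disjoint
train/validation/test membership runs inside `make_splits`.

Four regimes: within-cohort CV for adults and for pediatrics; external
validation (each adult-fold model evaluated on the entire pediatric cohort —
all five fold models are evaluated and averaged); and the enriched regime,
pooling both cohorts with cohort-stratified splits and cohort-stratified
reporting. Metrics are accuracy (%, threshold 0.5) and rank-based AUC (ties
counted half), aggregated as mean ± sample SD (n−1) over folds; a
single-class stratum reports AUC as undefined (`None`), never 0 or 1.

## Adversarial protocol

FGSM perturbs node features by `X + eps·sign(dL/dX)` with `L` the same
weighted BCE used in training, evaluated at the true label (untargeted,
loss-ascending; `sign(0) = 0`). Message passing always uses the clean
normalized adjacency, even though profile features are derived from it —
only `X` is attacked. Perturbed features are not clipped or re-symmetrized
by default (no projection step belongs to the attack; at `eps ≤ 1e-3`
violations of non-negativity are negligible), though both projections exist
as flags. The sweep runs `eps = 0` plus a geometric grid over
1e-5 … 1e-3 against each fold's own model (white-box) on the pediatric test
stratum of the enriched regime.

## Numerical choices and degenerate inputs

* Scores are clamped at 1e-12 before logs; sigmoid via the numerically
  stable library routine.
* Max pooling/aggregation breaks ties by first index (argmax), making
  gradients and runs deterministic.
* Asymmetric or negative adjacencies are rejected with the offending entry
  named; symmetry tolerance is 1e-8 relative to the largest weight.
* The perturbation-budget check `‖X_adv − X‖∞ ≤ eps` is exact up to the
  one-ulp rounding of measuring `(X + eps) − X` in float64.
* Seed fan-out for orchestrated experiments is
  `(global_seed·100003 + k) mod 2³¹`, with `k` a fixed registration index.

## Problem sizes

The test battery and the acceptance script run the study at the scaled-down
sizes the package adopts as its standard conditions: 60-region graphs for
signal, enrichment, ablation and attack experiments (300, 250 + 50
subjects), 30-region graphs for the five-model null calibration
(100 + 100 balanced subjects, five generator seeds), and the full 379-region
architecture only where it is cheap (parameter accounting, shape
contracts). Directional claims (enrichment benefit, skip ablation) are
averaged over five generator seeds.

## Known limitations

* The residual readout is one concrete interpretation of a skip-connected
  aggregation architecture; parameter counts for published residual variants
  are not matched (head dimensions unavailable).
* The generator's single global cohort shift is a coarse stand-in for
  protocol differences; no harmonization machinery is included.
* The planted sex effect is a log-mean shift on a fixed edge mask and is
  recoverable from a single propagation step; architectural advantages that
  real connectome data confers on multi-scale readouts (for example, a
  benefit from skip connections) need not reproduce on these conditions,
  and the directional ablation comparison can be a statistical tie.
* RF/SVM are fit with library defaults (plus PCA-100) by design; no
  hyperparameter search is performed for any model beyond the stated
  depth/pooling/skip grid.
* Only single-step FGSM is implemented — no iterative/PGD attacks, transfer
  attacks, or adversarial training.
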