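# Methods

`trisimnet` implements a patient-similarity-network pipeline for triage
decision support: a tabular emergency-admission cohort is preprocessed into
a feature matrix in [0, 1], converted into a thresholded similarity graph
whose nodes are patients, and a graph neural network is trained to assign
each node one of four triage severity codes. This note records the model,
the defaults and why, the numerical choices, and what the bundled synthetic
benchmark does and does not demonstrate.

## Preprocessing

The workflow is a fixed five-step composition:

1. **Cleaning.** Exact duplicate rows are dropped (first occurrence kept);
   rows with a missing severity label are dropped (they cannot supervise a
   node); rows missing a schema-mandatory demographic field (gender in the
   16-feature admission layout) are dropped. Every removal is counted in a
   provenance log, and `rows_in = rows_out + duplicates + missing_label +
   missing_mandatory` holds by construction.
2. **Mode imputation.** Remaining missing cells take their column's most
   frequent observed value. Ties are broken toward the smallest value under
   the column's natural ordering — an arbitrary but deterministic rule;
   reproducibility requires *some* fixed rule and the smallest-value choice
   is the simplest.
3. **Label encoding.** Categorical features and the target map to integers
   by lexicographic rank of their distinct values, making the encoding
   invertible and independent of row order.
4. **Class rebalancing.** Triage codes are heavily imbalanced. The default
   is SMOTE: each synthetic minority row is `x_i + u (x_nn − x_i)` with
   `u ~ U[0,1]` and `x_nn` one of the `k = 5` nearest same-class neighbours
   (Euclidean), oversampling every class to the majority count. `k = 5` is
   the canonical SMOTE default. A combined scheme (`smote_undersample`)
   SMOTEs classes below the median class size and randomly undersamples
   those above it — the natural choice for the ED-acuity layout where both
   directions are wanted. Balancing the whole cohort before the train/test
   split mirrors the workflow order (sampling before normalization and
   graph construction) but lets interpolated minority rows straddle splits;
   this is leakage-prone, so `run_experiment(split_before_balance=True)`
   offers a leakage-safe variant that splits first and SMOTEs training rows
   only. Reported benchmark numbers use the workflow order unless stated.
5. **Min–max scaling.** Each column maps to `(x − min)/(max − min)`.
   Constant columns map to 0 (the limit choice that avoids division by
   zero). Scaling last ensures synthetic SMOTE rows cannot push values
   outside [0, 1].

## Similarity graphs

Patients i, j are connected when the pairwise measure passes a *strict*
threshold: cosine similarity connects on `s > θ`, the distance measures
(Euclidean, Manhattan, Minkowski `(Σ|x_k − y_k|^p)^(1/p)`) on `d < θ`.
Strictness follows the definitions ("exceeds" / "lower than"); float ties
are measure-zero. Consequences asserted in the test suite: edge sets are
nested along a threshold grid, Minkowski at p = 1 and p = 2 reproduces
Manhattan and Euclidean exactly, and the Minkowski value is non-increasing
in p (so, at a fixed threshold, larger p can only *remove* edges — any
report of the opposite would indicate a non-standard convention, which this
package does not implement).

Edge weights store the raw cosine similarity or `1/(1 + d)` for distances.
Message passing ignores the weights: the convolution definitions used here
are stated over unweighted neighborhoods, and the weights are retained on
the graph for inspection and export. Pairwise values are computed in
512-row blocks against the full matrix with upper-triangle edge emission,
keeping memory O(block × n); `threshold_sweep` applies every threshold in
one pass. Self-similarity never creates self-loops.

## Architectures

Four node classifiers over F input features and C = 4 classes:

| family | layers | notes |
|---|---|---|
| `gcn5` | (F,64),(64,64),(64,64),(64,64),(64,C) | GCN, 20% dropout after hidden layers 2–4 |
| `gcn4` | (F,32),(32,32),(32,32),(32,C) | GCN, dropout after hidden layers 2–3 |
| `gatv2` | (F,8)×4 heads → (32,C) | GATv2 attention; one 20% dropout before each layer |
| `sage5` | (F,64),(64,32),(32,16),(16,8),(8,C) | GraphSAGE; max-pool aggregation, mean at layer 3; dropout after layer 4 |

ReLU follows every non-final layer. Putting ReLU on the output logits
would constrain them to be non-negative and interact badly with softmax
cross-entropy, so the final layer is linear everywhere. GCN uses the
renormalization form `D^{-1/2}(A+I)D^{-1/2} X W`; GATv2 scores edge j→i per
head as `a^T LeakyReLU(W_l x_j + W_r x_i)` with softmax over the
in-neighborhood (self-loop included); SAGE computes `W_r x_i + W_l agg`,
where max-pool `agg` is the elementwise max of `ReLU(W_p x_j + b_p)` over
neighbours and an empty neighborhood aggregates to zero — which makes
isolated nodes classifiable from their own features alone, and new
patients attachable and classifiable without retraining (inductive use).

The layers, a small reverse-mode autograd, Adam and the training loop are
implemented in numpy inside the package; every layer's analytic gradient is
checked against central finite differences in the test suite. The max-pool
subgradient is routed to the first element attaining each group maximum so
exact ties (e.g. duplicated rows) are not double-counted.

### Ablation variants

The ablation grid removes layer 2, 3, 4, or all three from `sage5`, at
hidden widths 8 and 64. How the surviving layers are re-dimensioned is a
genuinely open choice; this package re-chains the remaining hidden widths
as a geometric taper `w, w/2, w/4, …` floored at C, mirroring the base
model's tapering shape, and places the mean aggregator at the third layer
whenever the variant is at least three layers deep. Under this rule every
variant has strictly fewer parameters than the base model — the property an
ablation needs to be interpretable as capacity removal. (Giving all
remaining layers a uniform width of 64 would *exceed* the base capacity.)

## Training

Cross-entropy on the training-mask logits, Adam with weight decay 5e-4;
learning rate 0.01 (0.005 for `gatv2`). GCN/GAT train full-graph for up to
200 epochs. GraphSAGE trains on neighbor-sampled mini-batches: training
nodes are shuffled into seed sets of 3000, and a 5-hop subgraph grows per
set with at most 10 sampled in-edges per node per hop (matching the model's
depth; nodes at or below the fanout keep all neighbours, nodes above it are
sampled with replacement, which keeps the draw vectorizable while still
capping the in-degree).

Two schedule choices deserve explanation:

- **Epoch budget.** One epoch is one optimizer step per batch. On cohorts
  under the 3000-node batch size an epoch is a *single* step, so schedules
  tuned for multi-batch cohorts underfit badly. The GraphSAGE default is
  600 epochs with early stopping (patience 15 evaluations, validation
  checked every 10 epochs, best-on-validation weights restored).
- **Evaluation during sampled training.** A full-graph forward pass on a
  dense thresholded graph costs seconds per call and would dominate
  training if run every epoch. During mini-batch training the validation
  accuracy used for early stopping is therefore *estimated* by
  deterministic neighbor-sampled inference (same fanout, fixed seed);
  exact full-graph logits are always computed on the final model, and all
  reported accuracies and confusion matrices come from that exact pass.

A practical property worth knowing: with max-pool aggregation, a model
trained under fanout-10 sampling sees pooled maxima over ≤10 neighbours,
while full-graph inference pools over entire neighborhoods. On dense graphs
(average degree far above the fanout, e.g. cosine θ = 0.9 on scaled
nonnegative features) this shifts the pooled-feature distribution and slows
convergence — the reason for the long default schedule. Sparser graphs
(θ = 0.95) converge several times faster.

All randomness flows from `numpy.random.default_rng(seed)`; identical
(input, config, seed) reproduce bit-identical training histories. Training
raises an error on non-finite loss. Prediction is the argmax of the logits,
ties broken toward the smallest class index (numpy argmax order).

## Splits and evaluation

Stratified 70/30 train/test; 30% of the test rows are then re-assigned as a
validation set, so at n = 1000 the masks hold 700/90/210 train/val/test
rows and are pairwise disjoint. Accuracy is the primary metric; reports
also carry the C×C confusion matrix (rows = true class), per-class
precision/recall and macro-F1 as supplementary outputs. The tabular
baselines — SVM with an RBF kernel (C = 1) and k-NN (k = 5), both
scikit-learn defaults since nothing more specific is prescribed — use the
same prepared features and the same split seed as the graph experiments.

## Synthetic cohorts

The generator emits schema-conformant admission tables (16-feature and
14-feature ED layouts, 4-level targets) with controllable structure:

- numeric features are Gaussian clusters whose class centroids sit at
  pairwise distance `separation` (orthogonal-simplex construction) with
  within-class sd `noise_sd`, so `separation/noise_sd` controls Bayes
  separability; `separation = 0` removes all numeric class signal;
- categorical features are per-class tilted multinomials (strength
  `cat_strength`; 0 removes categorical signal);
- exact duplicates, missing feature cells and missing labels are injected
  at configurable rates *after* the clean table is built, on rows disjoint
  from the duplicated ones, and the injected counts are returned as ground
  truth so cleaning logs can be compared exactly.

Defaults: n = 6962 rows, class mix (0.10, 0.20, 0.30, 0.40) from most to
least severe (an imbalanced triage mix), missing-label rate 0.059 (the
dominant null mode in real admission tables), cell missingness 1%,
duplicate rate 1%, separation 4, noise sd 1. The generator reproduces the
schema and the failure modes of real cohorts — not their marginal
distributions, feature correlations, or measurement noise. Passing the
benchmark therefore shows the pipeline recovers known structure under
controlled conditions; it does not certify accuracy on any real cohort.

One geometric caveat: after min–max scaling all feature vectors live in the
nonnegative orthant, where cosine similarity is generically high, so loose
cosine thresholds (θ ≤ 0.9) produce very dense graphs whose edges mix
classes (label homophily drops toward the class-mix baseline). The same
effect — near-complete graphs at loose thresholds — occurs on real scaled
admission data; it is a property of thresholded cosine graphs, not of the
generator.

## Known limitations

- SMOTE-before-split (the workflow order) inflates test accuracy through
  interpolation leakage; use `split_before_balance=True` for honest
  held-out estimates.
- The GNN core is plain numpy: adequate for cohorts of a few thousand
  patients on one CPU, not for very large graphs or GPUs.
- Graph construction is exact O(n²) pairwise; no approximate-neighbor
  sparsification is offered (thresholding, not k-NN, defines the model).
- Categorical features enter as integer codes, not one-hot; with many
  levels this imposes an artificial ordering (it matches the stated
  label-encoding design).
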