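# trisimnet

Patient-similarity networks and graph neural network classifiers for
emergency-department triage severity prediction.

Emergency triage assigns each arriving patient a 4-level severity code
(immediate / urgent / deferrable / minor) from vitals, symptoms and
biochemistry. `trisimnet` frames this as *node classification on a patient
similarity network*: every patient is a node carrying its feature vector,
an edge connects two patients whose vectors pass a similarity threshold,
and a graph neural network predicts each node's code from its features and
neighborhood. Because the embedding is inductive, a newly arrived patient
can be attached to the network and scored without retraining. The package
is aimed at clinical-informatics researchers studying similarity-network
triage models and their sensitivity to design choices.

## The model

Given a preprocessed cohort `X ∈ [0,1]^{n×F}` with labels
`y ∈ {0..C−1}^n`, an edge set is built by strict thresholding of a
pairwise measure:

- cosine similarity: `(i,j) ∈ E  ⇔  cos(x_i, x_j) > θ`
- Euclidean / Manhattan / Minkowski-p distance:
  `(i,j) ∈ E  ⇔  d(x_i, x_j) < θ`, with
  `d_p(x,y) = (Σ_k |x_k − y_k|^p)^{1/p}`

Three GNN families classify the nodes: a 5-layer and a 4-layer GCN
(`X' = D^{−1/2}(A+I)D^{−1/2} X W`), a 2-layer GATv2 with 4 attention
heads, and a 5-layer GraphSAGE (`h_i = W_r x_i + W_l agg_{j∈N(i)} x_j`,
max-pool/mean aggregation) trained on neighbor-sampled mini-batches
(batch 3000, fanout 10, 5 hops). Training minimizes cross-entropy with
Adam (lr 0.01, 0.005 for attention; weight decay 5e-4). Preprocessing
follows a fixed workflow: deduplicate and drop null-label rows → mode
imputation → label encoding → SMOTE class balancing → min–max scaling.
The experiment layer reproduces threshold-sensitivity sweeps, a GraphSAGE
layer-ablation grid and SVM/k-NN tabular baselines. A bundled synthetic
cohort generator with controllable class separation makes every stage
testable without clinical data. See `docs/methods.md` for the full
account.

## Worked example

```python
import trisimnet as tsn
from trisimnet.model import TriageGNN

spec = tsn.CohortSpec(n=800, separation=6.0, seed=42)   # separable 4-class cohort
raw, truth = tsn.generate_cohort(spec)                  # schema-conformant table
pc = tsn.preprocess(raw)                                # clean->impute->encode->SMOTE->scale
g = tsn.build_graph(pc, tsn.MetricSpec("cosine", 0.95))
res = TriageGNN(g, arch="sage5", split_seed=0).fit(seed=0, epochs=300)
print(res.summary())
```

prints

```
Triage similarity-network classifier
====================================================
architecture:      sage5
layers:            (16, 64) -> (64, 32) -> (32, 16) -> (16, 8) -> (8, 4)
parameters:        12388
nodes / edges:     1212 / 50325
isolated nodes:    10
metric:            cosine (threshold 0.95)
epochs run:        210
----------------------------------------------------
train_accuracy:    0.9835
validation_accuracy:0.9727
test_accuracy:     0.9843
macro F1:          0.9842
----------------------------------------------------
class                precision    recall  n_test
Green                    0.984     0.968      63
Orange                   1.000     0.984      63
Red                      0.985     1.000      64
Yellow                   0.969     0.984      64
```

The 800 generated rows grow to 1212 nodes after SMOTE equalizes the four
severity classes; at cosine threshold 0.95 the network keeps 50k edges and
10 patients remain isolated (they are still classified, from their own
features). Test accuracy 0.984 against a 0.25 majority baseline shows the
pipeline recovers the generator's planted class structure; `res.predict_new(x)`
scores unseen patients inductively, and
`tsn.sensitivity_analysis`, `tsn.ablation_study` and
`tsn.tabular_baselines` reproduce the sweep, ablation and baseline
experiments (reports carry confusion matrices and per-class
precision/recall).

A CLI mirrors the library:

```bash
trisimnet synth --schema kaggle16 --n 2000 --seed 7 --out cohort.csv
trisimnet preprocess --in cohort.csv --schema kaggle16 --out prepared/
trisimnet sweep --in prepared/ --metric cosine --thresholds 0.98,0.95,0.90
trisimnet train --in prepared/ --arch sage5 --metric cosine --threshold 0.95
```

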