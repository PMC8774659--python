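# ergcn

Cancer-subtype classification from gene-expression profiles using a residual
graph convolutional network over a patient similarity network.

Molecular subtypes (e.g. BRCA Basal/LumA/LumB/Her2) differ in prognosis and
treatment response, but cohorts with curated subtype labels are small — often
a hundred or two patients against tens of thousands of genes. This package
targets exactly that regime: instead of classifying each expression profile in
isolation, it links patients whose profiles are strongly correlated and lets a
graph neural network pool evidence across similar patients.

## Model

Given an expression matrix `X ∈ R^{m×n}` (m samples × n genes):

1. **Similarity network.** `r_ij` = Pearson correlation of samples i and j;
   edge `A_ij = 1` iff `|r_ij| > θ`; every node keeps a self-loop
   (`A_ii = 1`). `S = D^{-1/2} A D^{-1/2}` is the symmetric normalization.
2. **Residual two-layer GCN.**

       H1     = relu(S X W1)
       Hp     = H1 + relu(X W_skip + b_skip)
       P      = softmax(S Hp W2)

   The skip connection re-injects a learned transform of the raw profiles
   after the first aggregation, countering the over-smoothing that dense
   similarity graphs induce. Training minimizes the cross-entropy
   `L = −Σ_{d∈T} ln P[d, y_d]` over training nodes T with full-batch Adam;
   the graph spans all samples (transductive learning).

Around the model sit the evaluation machinery (accuracy, macro
precision/recall/F1, multiclass MCC, pair-count adjusted Rand index,
silhouette width, Davies–Bouldin index — each validated against definitional
oracles), the experimental protocols (repeated stratified 5-fold transductive
CV, threshold sweep, leave-one-out new-sample augmentation, MLP/GCN ablation),
random-forest Gini ranking of subtype-driving genes, and a synthetic-data
generator with known subtype structure so the entire pipeline is testable
offline. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from ergcn import ModelConfig, cross_validate, default_benchmark
from ergcn.experiments import CrossValidationPlan

data = default_benchmark()          # 120 samples, 400 genes, 4 subtypes
mean, std, reports = cross_validate(
    data.expr, data.labels, theta=0.5,
    config=ModelConfig(seed=0),
    plan=CrossValidationPlan(folds=5, repeats=2, seed=0),
)
print(f"accuracy  {mean.accuracy:.4f} +/- {std['accuracy']:.4f}")
print(f"macro F1  {mean.f1:.4f}")
print(f"MCC       {mean.mcc:.4f}")
print(f"ARI       {mean.ari:.4f}")
print(f"silhouette (embeddings) {mean.silhouette:.4f}")
print(f"silhouette (raw)        {np.nanmean([r.metadata['silhouette_raw'] for r in reports]):.4f}")
```

prints

```
accuracy  1.0000 +/- 0.0000
macro F1  1.0000
MCC       1.0000
ARI       1.0000
silhouette (embeddings) 0.5794
silhouette (raw)        0.2622
```

The benchmark's four subtypes are strongly separated (within-subtype
correlation ≈0.65 vs ≈0.33 between), so held-out classification is perfect;
the interesting number is the silhouette pair: the learned embeddings `Hp`
separate the predicted subtypes more than twice as cleanly as the raw
expression space, which is the residual GCN's representation-learning effect.
Real cohorts have far weaker structure — the benchmark certifies correctness,
not real-data performance.

The same pipeline is available from the shell:

```
ergcn simulate --m 120 --n 400 --classes 4 --effect 3.0 --seed 0 \
      --out-expr expr.tsv --out-labels labels.tsv
ergcn cv --expr expr.tsv --labels labels.tsv --theta 0.5 --out cv.jsonl
ergcn new-sample --expr expr.tsv --labels labels.tsv --theta 0.5 --out ns.jsonl
ergcn train --expr expr.tsv --labels labels.tsv --theta 0.5 --out-pred pred.tsv
ergcn key-genes --expr expr.tsv --pred pred.tsv --k 50 --out genes.tsv
```

For real cohorts, expression input is a delimited table (samples as rows,
header row of gene ids, first column sample ids; `--transpose` for
genes-as-rows) and labels a two-column `sample_id<TAB>subtype` table. θ is
dataset-dependent — values near 0.4 suit BRCA- and LUNG-scale cohorts while
GBM cohorts need around 0.8 — and `ergcn sweep` explores the grid.

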