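# Methods

## Model

The classifier is a transductive node-classification model on a patient
similarity network. Given an expression matrix `X ∈ R^{m×n}` (m samples, n
genes), the network is built in two steps:

1. **Similarity.** `r_ij` is the Pearson correlation between the expression
   profiles of samples i and j.
2. **Thresholding.** `A_ij = 1` iff `|r_ij| > θ` (strict inequality, raw
   double-precision comparison, no rounding), with `A_ii = 1` for every node.
   Strongly anti-correlated samples are deliberately connected: the absolute
   value treats correlation magnitude, not sign, as evidence of relatedness.

Self-loops are added *before* the degree matrix `D = diag(A·1)` is computed,
so every degree is at least 1 and the symmetric normalization
`S = D^{-1/2} A D^{-1/2}` is always defined. Isolated samples keep their
self-loop and are never dropped — every sample must receive a prediction.
All eigenvalues of `S` lie in `[-1, 1]`.

The classifier itself is a two-layer GCN with a residual skip from the raw
features:

    H1     = relu(S X W1)
    Hp     = H1 + relu(X W_skip + b_skip)
    logits = S Hp W2
    P      = row-softmax(logits)

The skip term exists to counter over-smoothing: on a dense similarity graph,
two applications of `S` drive node representations toward the graph mean, and
the re-injected transform of the raw profiles preserves per-sample identity.
`Hp` is the latent embedding used for internal (clustering-validity) metrics.

The GCN layers carry no bias (the propagation rule is the bare `S·H·W`
product); the skip map is affine. The loss is the *summed* cross-entropy
`L = -Σ_{d∈T} ln P[d, y_d]` over the training mask T only; probabilities are
clipped at 1e-12 before the log, and softmax uses max-subtraction. Training is
full-batch Adam (β₁=0.9, β₂=0.999, ε=1e-8). Because the graph spans all
samples while only training labels enter the loss, the scheme is transductive;
this differs from fully inductive evaluation and is stated prominently
wherever cross-validation results are reported.

Forward and backward passes are explicit numpy; gradients are analytic and
verified against central finite differences (1e-4 relative on a 6-sample
instance) in the test suite.

### Ablation variants

`gcn` removes the skip term (`Hp = H1`); `mlp` removes the graph entirely
(`relu(X W1)` then `W2`, no `S` anywhere). Both share parameter shapes and
all other hyperparameters with the full model, so differences isolate the
contribution of the graph and of the residual connection.

## Hyperparameters

| parameter | default | notes |
|---|---|---|
| hidden_dim | 64 | width of the first layer; second layer width is F (number of subtypes) |
| learning_rate | 0.001 | Adam |
| epochs | 200 | full-batch; typical for 2-layer GCNs at this rate — loss curves are returned so users can adjust |
| dropout_rate | 0.5 | applied to Hp (between residual sum and second layer), training only |
| θ | data-dependent | e.g. 0.42 (BRCA-like), 0.41 (LUNG-like), 0.8 (GBM-like); 0.5 for the synthetic benchmark |
| init | Glorot uniform, seeded | biases zero |

Dropout placement and the affine (rather than purely linear) skip are design
choices: dropout sits at the standard position in two-layer GCNs, and the skip
map is read as affine because a learned bias costs nothing and subsumes the
linear case.

Expression values are used exactly as provided — no log transform, z-scoring
or gene filtering happens internally. Users who want normalized input must
normalize upstream.

## Evaluation metrics

External metrics compare predicted to true labels: accuracy, macro-averaged
one-vs-rest precision/recall/F1 (macro, not micro: with a micro average the
three would collapse onto accuracy, which is not the behaviour this family of
multiclass reports shows; the averaging scheme is switchable), the multiclass
Matthews correlation computed from the full confusion matrix (which reduces
exactly to the familiar binary formula at F=2), and the pair-counting adjusted
Rand index.

Two ARI formulas are exposed. The default is the standard Hubert–Arabie
pair-count form `2(TP·TN − FP·FN)/((TP+FP)(FP+TN)+(TP+FN)(FN+TN))` over the
m(m−1)/2 unordered sample pairs. An alternative literal form
`(RI − E)/(max − E)` with `RI=(TP+TN)/total`, `E=(TP+TN)(TP+FP)/total`,
`max=((TP+TN)+(TP+FP))/2` appears in parts of the subtype-classification
literature; it mixes count and fraction scales, can go strongly negative on
mild disagreements and does not return 1 even for identical partitions, so it
is kept only as an explicitly requested option (`formula="eq10"`).

Internal metrics score the predicted partition's geometry under Euclidean
distance: mean silhouette width `(b−a)/max(a,b)` (singleton clusters score 0)
and the Davies–Bouldin index. Both are computed from exact
root-sum-of-squares distances so they agree with their definitional formulas
to full double precision. By default they are evaluated on the learned
embeddings `Hp` with *predicted* labels, restricted to the held-out samples of
each fold; the raw-expression feature space is retained as an option and
reported alongside for comparison.

Degenerate-case conventions (all logged with warnings): zero-denominator
per-class precision/recall contribute 0 to the macro mean; degenerate MCC and
ARI denominators give 0; a fold whose predictions form a single cluster gets
NaN internal metrics and is excluded from internal-metric averages.

## Experimental protocols

**Repeated stratified 5-fold transductive CV** (default 10 repeats = 50
fold-runs): the network is built once from all samples; each run trains with
the loss masked to four folds and scores the held-out fold from the same
full-graph forward pass. Folds are stratified because cohorts of 85–213
samples with 4 subtypes frequently lose a class in unstratified folds.
Metrics are computed per fold-run and then averaged (mean ± SD over runs).
Every run's seed derives deterministically from (config seed, repeat, fold).

**Threshold sweep**: the same CV at each θ on a grid spanning 0.1–0.9 (0.05
steps, refined to 0.01 around 0.40–0.45 and 0.78–0.82 where similarity graphs
of this kind typically peak); edge counts are logged per θ and are
non-increasing by construction.

**New-sample protocol** (leave-one-out): for each sample, the model is
trained on the other m−1 samples' network; the held-out sample is then
attached to that network by correlating it against the training samples and
re-normalizing — the m×m training adjacency block is unchanged — and a single
forward pass yields its prediction. The model is *not* retrained after
augmentation. External metrics aggregate the m collected single-sample
predictions.

**Ablation**: mlp / gcn / ergcn cross-validated under identical fold
assignments and seeds.

## Key-gene ranking

A random forest (default 500 trees, unlimited depth, Gini criterion, seeded)
is fit on the expression matrix against the model-predicted labels; genes are
ranked by mean Gini impurity decrease (sklearn's normalized convention:
importances sum to 1), ties broken lexicographically by gene id. The top-k
(default 50) list is exported as a plain two-column table for downstream
enrichment tools. Forest size is a stability choice — rankings are averaged
over many trees rather than repeated fits.

## Synthetic benchmark

The generator draws `x_ij = b_j + δ·1[j ∈ signature(class_i)] + ε_ij` with
gene baselines `b_j ~ N(0, τ²)` shared across samples and noise
`ε ~ N(0, σ²)`. The shared baseline puts a correlation floor of `τ²/(τ²+σ²)`
between any two samples; each subtype's disjoint block of g signature genes
shifts means by δ, raising within-subtype correlation above that floor. Class
sizes follow the requested proportions with largest-remainder rounding.

The default benchmark is m=120, n=400, F=4 equal subtypes, g=40, δ=3, σ=τ=1,
seed 0 — sized like the small TCGA subtype cohorts (85–213 samples) this
pipeline targets. At these settings within-class correlation is ≈0.65 and
between-class ≈0.33, so the benchmark threshold θ=0.5 (the midpoint) separates
the subtypes cleanly. A Gaussian model is used deliberately: the pipeline
consumes only correlations and real-valued features, so count-level realism
(negative-binomial noise, library-size effects, batch structure, dropout)
would add nothing to correctness testing. Consequently, passing on this
benchmark demonstrates that the machinery is correct and well calibrated —
near-perfect accuracy here does **not** predict accuracy on real TCGA
matrices, whose class structure is far weaker and noisier.

Null calibration uses the same generator with δ=0 (labels carry no signal):
CV accuracy must sit at 1/F and pair-count ARI at 0, within sampling error.

## Problem sizes used in tests and the acceptance script

The shipped test suite runs the full 10×5-fold CV and the full m=120
leave-one-out protocol on the default benchmark (each fold-run trains 200
epochs in well under a second in pure numpy); unit tests of the experiment
layer use a smaller m=60, F=3 cohort with the same correlation structure, and
the ablation check uses 2 CV repeats. The acceptance script executes every
protocol end-to-end at these sizes in about two minutes.

## Known limitations

- Transductive only: a genuinely new sample requires the augmentation
  protocol; there is no inductive forward pass over an unseen graph.
- Full-batch dense linear algebra: memory and time scale as O(m²·h + m·n·h),
  fine for cohorts of hundreds, not for tens of thousands.
- The similarity graph is unweighted; correlation strength beyond the
  threshold is discarded.
- No internal normalization: results depend on the upstream preprocessing of
  the expression matrix, and θ must be re-tuned per dataset (the sweep exists
  for exactly this).
- Exact numeric reproduction of previously reported TCGA results is a
  documented exercise rather than a guarantee: epoch counts, dropout rates and
  fold seeds behind such results are typically unpublished.
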