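# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical and design decisions taken where the design was genuinely open.

## Data model and preprocessing

Inputs are per-omics matrices (samples × features, CSV/TSV, first column
sample IDs, header row feature IDs) and a survival table
(`sample_id, time, event`). Loading aligns everything to the intersection
of sample IDs in the survival table's order; an empty intersection is
fatal.

Preprocessing per omics layer, in order:

1. drop features with more than `missing_threshold` (default 10%) missing
   entries (empty cell, `NA`, `NaN`, case-insensitive);
2. impute remaining missing values with the per-feature median of observed
   values;
3. `log2(x+1)` if the layer is nonnegative (expression-like); skipped with
   a warning when negative values are present (e.g. methylation M-values,
   already-standardised data) — the base and pseudocount are conventions,
   not estimates;
4. drop zero-variance features, keep the `top_k` highest-variance features
   (variance ties broken by original column order); low-variance removal is
   realised as top-k ranking because the target dimensionality, not a
   variance threshold, is the quantity one typically fixes (e.g. 6000
   gene / 600 microRNA features at cohort scale);
5. standardise each kept feature to mean 0, sd 1.

For any train/test protocol the pipeline statistics (missingness, medians,
variance ranking, means/sds) are fit on training samples only and applied
unchanged to held-out samples. This is the leak-free order; fitting the
pipeline before splitting is possible by preprocessing the full cohort
first, but it is not what the evaluation harness does.

## Sample graphs

Per omics layer: a directed KNN graph (self excluded) with kernel weights
`w(i,j) = exp(−ρ²(x_i,x_j)/(μ δ²))`, where `δ²` is the median squared
Euclidean distance over unordered distinct sample pairs and `μ` a
per-layer bandwidth (defaults 0.3 for the first, gene-like, layer and 0.2
for the second, microRNA-like, layer; further layers 0.3). `δ² = 0` (all
samples identical) is fatal. The directed graph is symmetrised with an
elementwise max — the union of directed edges, preserving kernel values;
averaging instead would halve one-sided weights here and then again at
fusion. Layers are fused by the elementwise mean (union of edge sets; an
edge present in one of L layers contributes value/L), and the convolution
matrix is `Â = D̃^{-1/2}(A+I)D̃^{-1/2}`, always well defined because the
self-loop makes every degree ≥ 1. Attention neighbourhoods `N_i` are the
positive entries of row i of `Â`, which include i itself.

Graphs are built on preprocessed features, not on latent embeddings: the
kernel is defined on the observed `x_i`, and building it on trainable
embeddings would make the graph drift during optimisation.

**Inductive test attachment.** Training and evaluation use a graph over
the training samples. Held-out samples are attached by KNN to training
samples only, reusing the training `δ²` and `μ`; test–test edges are
excluded, and `Â` is recomputed on the combined graph. Test outcomes never
enter graph construction, preprocessing statistics or the loss (asserted
by a taint test).

## Attention blocks

*Inter-omics*: one affine embedding per layer into `d_latent`; per head a
shared query/value pair applied to every layer (keys coincide with queries
to reduce parameters); attention logits `⟨q_i^{u1}, q_i^{u2}⟩ / d_c`,
softmax over the source layer index; the per-layer contextualised vectors
are stacked along features. The block requires ≥ 2 layers and generalises
to any number (the attention matrix per sample is v × v row-stochastic).
Heads are compressed by one *shared* linear map and concatenated; whether
the shared map is intended per-head is ambiguous, and the shared form is
kept as the parameter-reduction reading.

*Inter-sample*: plain attention is `rowsoftmax(QQᵀ/d)V` over all samples;
the structure-biased form multiplies each kernel entry by `Â(i,j)` before
row normalisation, so support is exactly the fused-graph neighbourhood.
Scores outside the support are masked before exponentiation and each row
is shifted by its support maximum (detached), which makes the operation
exactly local — perturbing a non-neighbour cannot change row i even in
floating point — and overflow-safe. One attention head, one layer: the
architecture stacks nothing deeper. A GCN-style layer `f(Â Z^c W)` serves
as the fixed-weight aggregation ablation.

The attention divisor is the raw projection width `d` (`attention_scale:
dim`), kept exactly as the architecture defines it even though `sqrt(d)`
is the common convention; `attention_scale: sqrt_dim` switches to the
conventional scaling for sensitivity analysis.

## Cox head

The loss is the negative log partial likelihood with the standard
*inclusive* risk set `R(t) = {j: O_j ≥ t}` and Breslow handling of ties.
A `strict` flag implements the risk set `{j: O_j > t}` instead; under it
events with an empty risk set (always the last event) are skipped. The
strict form is retained only for comparison — it is ill-defined at the
maximum event time, which is why the inclusive form is the default. The
log-sum-exp is computed shift-stabilised; with no events the loss is 0
with a warning. `β` is a bias-free linear map trained jointly with all
other parameters. The Breslow estimator provides the cumulative baseline
hazard (increments `d(t)/Σ_{j∈R(t)} exp(s_j)` at distinct event times);
survival curves are `S_i(t) = exp(−Λ₀(t) e^{s_i})`. With all scores zero
the Breslow estimator reduces exactly to Nelson–Aalen.

## Metrics

*Concordance index*: over ordered pairs with `O_i < O_j` and `Δ_i = 1`
(pairs whose shorter time is censored, censored–censored pairs, and
tied-time pairs are excluded), the fraction with `s_i > s_j`; score ties
count 1/2 (ties are not otherwise specified; simulated continuous scores
make them measure-zero).

*Time-dependent AUC*: pooled over distinct event times t, pairs
`O_i < t < O_j` (strict inequalities; tied times contribute no pair),
correct if `s_i > s_j`, normalised by the total number of enumerated
pairs. The index i is *not* restricted to event cases by default — that is
the formula as defined; `cases="events_only"` gives the conventional
cumulative/dynamic variant. Both metrics are verified exactly against
brute-force pair enumeration.

*Risk stratification*: median split (scores strictly above the median are
high-risk; an empty group is fatal), Kaplan–Meier curves per group and the
two-sample log-rank test, all via lifelines.

## Synthetic cohorts

The generator emulates the structure the model targets: latent sample
clusters shift all layers coherently (so KNN graphs recover them), shared
latent factors tie layers together, and the true log-hazard is

    η_i = a·(standardised linear term, sparse weights per layer)
        + b·(standardised sum of cross-layer feature products)
        + c·(per-cluster frailty offset)

with defaults a = 2.5, b = 1.5, c = 2.5 chosen once so that the oracle
discrimination of η on its own outcomes exceeds C ≈ 0.85–0.9 — a "strong
signal" regime in which learning curves are informative at n of a few
hundred. Event times are Weibull via inverse-transform sampling (the shape
parameter does not affect rankings, only the time scale); censoring is an
independent exponential whose rate is calibrated by bisection to a target
fraction (default 25%). The truth record stores η (the Bayes-optimal risk
score), weights, interaction pairs and cluster labels.

What the generator does **not** emulate: count-like RNA-seq marginals,
heavy feature correlation blocks, batch effects, and — importantly —
*measurement noise that is independent of the hazard*: η is a function of
the observed feature values, so a per-sample model can in principle
recover all of it, and inter-sample aggregation carries no extra
information. Passing tests on these cohorts therefore demonstrate correct
mechanics and learnability, not the real-data advantage of neighbourhood
sharing, which arises when observed features are noisy proxies of the
prognostic state. Consistent with this, on these cohorts the ablations
without one of the two attention stages score on par with (n=400: slightly
above) the full collaborative model — the expected behaviour given the
generator's construction, and the reason ablation comparisons here are
directional checks rather than benchmarks.

## Training and evaluation defaults

Full-batch Adam (the partial likelihood couples all samples through risk
sets, so mini-batching would change the objective) at learning rate 2e-4;
600 epochs by default — at desk scale (n ≈ 300–500, p ≈ 100) the loss has
plateaued well before that and longer schedules do not change held-out
discrimination; no early stopping, so runs are deterministic given the
seed. Widths: `d_latent` 64, `d_c` 64, 2 heads with combiner output 64
(combined width 128), `d_attn` 128, `d_h` 64; ReLU activations. Query
weights are initialised with gain 4 over the fan-in bound so attention
logits (divided by the full width d) start at order one; with gain 1 the
softmax starts nearly uniform and sharpens too slowly to matter. Weight
decay and dropout are off by default and config-exposed. The
neighbourhood size K (default 15) is the one hyperparameter with a
selection routine: inner cross-validation over a grid, exact ties going to
the smaller K.

Repeated holdout: 80/20 random splits, default 50 repeats, preprocessing
and graph refit on each training split, inductive scoring of the test
fifth, C-index/AUC summarised as mean ± sd. Splits without events in both
parts are redrawn (capped, with a warning).

Serialisation writes one `.npz` archive (parameters, preprocessing
statistics, graph, training features and outcomes for baseline/attachment)
and round-trips predictions bit-exactly.

## Numerical notes and degenerate inputs

- All softmax-type operations subtract a detached maximum; for ratio
  normalisations this is exact, not approximate.
- Dense masking is used for the sparse neighbourhood attention; fine up to
  a few thousand samples, which is the intended scale.
- Zero-variance features are dropped before variance ranking; zero-variance
  hidden nodes are skipped (with a warning) in the correlation analysis;
  constant risk scores make the median split fatal by design.
- The autodiff engine covers exactly the primitives the model needs and is
  gradient-checked against central finite differences; the Cox loss
  gradient is additionally checked end-to-end.

## Known limitations

- Single attention head and single layer in the inter-sample block; no
  feed-forward, residual or layer-norm sublayers — deliberately, as the
  architecture defines none.
- No IPCW (Uno-type) correction in C-index/AUC; estimates are biased under
  heavy, covariate-dependent censoring.
- The Breslow tie convention only (no Efron correction).
- Desk-scale by design: dense n × n attention and full-batch training.
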