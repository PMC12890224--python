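# survformer

Collaborative attention networks for multi-omics survival analysis with a
Cox proportional-hazards head.

## The problem

Cancer prognosis modelling increasingly draws on several omics layers per
patient — gene expression, microRNA expression, DNA methylation — each a
high-dimensional matrix over the same samples, paired with right-censored
survival outcomes (an observed time `O_i` and an event indicator
`Δ_i ∈ {0,1}`). Two kinds of structure matter beyond per-feature effects:
*cross-omics interactions* (a gene's effect modulated by a microRNA, say)
and *inter-sample neighbourhood structure* (molecularly similar patients
share risk profiles). This package implements a deep survival model that
targets both at once, for biostatisticians who want a tested, desk-scale
reference implementation with a synthetic-cohort generator so every stage
can be exercised without any data download.

## The model

Two attention mechanisms run in sequence on preprocessed omics matrices
`X^(l)`:

1. **Inter-omics attention** (within each sample, across layers). Each
   layer is embedded by one affine map, `Z^(l) = f(X^(l) W^(l) + b)`. A
   shared projection pair per head (keys ≡ queries, to halve parameters)
   gives `q_i^(l) = W_Q^c z_i^(l)`, `v_i^(l) = W_V^c z_i^(l)`, and

       α_i^{u1,u2} = ⟨q_i^(u1), q_i^(u2)⟩ / d_c   (softmax over u2)
       z_i^{u1,c} = Σ_{u2} α̂_i^{u1,u2} v_i^(u2),

   stacked over source layers `u1` and, across heads, compressed by a
   shared linear map and concatenated into `Z^c`. The divisor is the raw
   width `d_c` (a `sqrt_dim` switch gives the conventional scaling).

2. **Graph-biased inter-sample attention.** Per-omics K-nearest-neighbour
   graphs with exponential kernel weights
   `exp(−ρ²(x_i,x_j)/(μ δ²))` (`δ²` = median pairwise squared distance) are
   fused by averaging and spectrally normalised to
   `Â = D̃^{-1/2}(A + I)D̃^{-1/2}`. The attention kernel on `Q = Z^c W_Q` is
   multiplied entrywise by `Â`, restricting support to graph
   neighbourhoods:

       α̂(i,j) = exp(q_i·q_j/d) Â(i,j) / Σ_{j'∈N_i} exp(q_i·q_j'/d) Â(i,j').

   The aggregated embeddings are projected (`z_i^h = f(z_i W_1)`) and a
   bias-free linear map gives the risk score `s_i = β·z_i^h`.

Everything is trained end-to-end by the negative log Cox partial likelihood

    L = − Σ_{i: Δ_i=1} [ s_i − log Σ_{j: O_j ≥ O_i} exp(s_j) ],

full-batch Adam at learning rate 2e-4; the Breslow estimator then provides
the baseline cumulative hazard for survival curves. Evaluation follows a
repeated 80/20 holdout protocol with the concordance index, a time-pooled
AUC, and Kaplan–Meier risk stratification with log-rank testing. Ablation
variants (`single_graph`, `concat_graph`, `cross_only`, `cross_gcn`,
`cross_attn`) rewire the same blocks to isolate each mechanism. Held-out
samples are scored inductively: they attach to their nearest *training*
samples only, and test outcomes never touch training.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from survformer import (SimConfig, ModelConfig, simulate_cohort, fit_pipeline,
                        concordance_index, time_dependent_auc, km_logrank)

omics, surv, truth = simulate_cohort(SimConfig(n=400, seed=0))
oracle_c, _ = concordance_index(truth["eta"], surv)

rng = np.random.default_rng(1)
idx = rng.permutation(len(surv))
train_idx, test_idx = idx[:320], idx[320:]
pipe = fit_pipeline([m.subset(train_idx) for m in omics],
                    surv.subset(train_idx), ModelConfig(variant="full", seed=0))

scores = pipe.predict_risk([m.subset(test_idx) for m in omics])
surv_test = surv.subset(test_idx)
c, n_pairs = concordance_index(scores, surv_test)
auc, _ = time_dependent_auc(scores, surv_test)
strat = km_logrank(scores, surv_test)
```

Output:

```
cohort: n=400, events=298, censoring=0.26
oracle C-index of the true log-hazard: 0.909
training loss: 1201.4 -> 412.3
held-out C-index: 0.863 (2907 comparable pairs)
held-out time-dependent AUC: 0.936
log-rank chi2 = 71.6, p = 2.60e-17
```

The oracle C-index (0.909) is the discrimination of the *true* log-hazard
on its own simulated outcomes — an upper benchmark no fitted model should
exceed beyond sampling noise. The fitted model reaches 0.863 on the 80
held-out samples, and its median-split risk groups separate strongly
(log-rank p ≈ 1e-17).

The same flows are available from the shell:

```bash
survformer simulate --n 400 --seed 0 --out-dir cohort/
survformer evaluate --omics cohort/omics1.csv --omics cohort/omics2.csv \
    --survival cohort/survival.csv --variant full --n-repeats 10 --seed 0
survformer ablate --omics cohort/omics1.csv --omics cohort/omics2.csv \
    --survival cohort/survival.csv --n-repeats 10
```

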