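"""Model assembly, training, repeated-holdout evaluation and analysis.

The full model wires the blocks in sequence: per-omics affine embedding ->
inter-omics multi-head attention -> head combination -> structure-biased
inter-sample attention on the fused KNN graph -> projection -> linear Cox
risk score, trained end-to-end by the negative log partial likelihood with
full-batch Adam (the partial likelihood couples all samples through risk
sets, so mini-batching would change the objective).

Ablation variants rewire the same blocks:

================  ==========================================================
``full``          complete collaborative model (cross-omics + graph-biased
                  inter-sample attention)
``single_graph``  one omics layer with its own graph; no cross-omics block
``concat_graph``  concatenated per-omics embeddings into the graph-biased
                  attention; no cross-omics block
``cross_only``    cross-omics features straight into the Cox head; no
                  inter-sample block
``cross_gcn``     cross-omics features aggregated by a fixed-weight GCN
                  layer on the fused graph; attention ablated
``cross_attn``    cross-omics features through plain (graph-free) attention
================  ==========================================================

Held-out samples are scored inductively: preprocessing statistics and the
graph kernel scale come from training samples only, test samples attach to
their nearest training samples, and a forward pass over the combined cohort
yields test risk scores.  Test outcomes never touch training.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, concat
from .attention import (
    combine_heads,
    cross_omics_attention,
    embed_omics,
    gcn_layer,
    init_affine,
    plain_attention,
    project_embeddings,
    structure_biased_attention,
)
from .cox import BreslowBaseline, CoxHead, breslow_baseline, cox_partial_loss_tensor
from .graph import FusedGraph, attach_test_samples, build_fused_graph, default_mu
from .io import OmicsMatrix, Preprocessor, SurvivalTable
from .metrics import EvalResult, concordance_index, time_dependent_auc

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "Model",
    "build_model",
    "fit",
    "FittedPipeline",
    "fit_pipeline",
    "repeated_holdout",
    "select_K",
    "feature_correlation_analysis",
]

VARIANTS = ("full", "single_graph", "concat_graph", "cross_only", "cross_gcn",
            "cross_attn")

_NEEDS_CROSS = {"full", "cross_only", "cross_gcn", "cross_attn"}
_NEEDS_GRAPH = {"full", "single_graph", "concat_graph", "cross_gcn"}
_HAS_SAMPLE_ATTENTION = {"full", "single_graph", "concat_graph", "cross_attn"}


@dataclass
class ModelConfig:
    """All tunable settings of the model and its training loop."""

    variant: str = "full"
    d_latent: int = 64     # per-omics embedding width
    d_c: int = 64          # inter-omics query/value width (attention divisor)
    n_heads: int = 2
    d_head_out: int = 64   # per-head output width after the shared combiner
    d_attn: int = 128      # inter-sample query/value width (attention divisor)
    d_h: int = 64          # final projected embedding width
    query_gain: float = 4.0  # init gain on query weights (order-one logits)
    activation: str = "relu"
    attention_scale: str = "dim"   # divisor d as printed; "sqrt_dim" for sqrt(d)
    epochs: int = 600
    lr: float = 2e-4
    weight_decay: float = 0.0
    strict_risk_set: bool = False
    omics_index: int = 0   # layer used by the single_graph variant
    K: int = 15            # KNN neighbourhood size
    mus: list | None = None
    top_k: int | None = None       # preprocessing variance filter (None: keep all)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")


class Model:
    """Learnable parameters and the forward pass for one model variant."""

    def __init__(self, cfg: ModelConfig, feature_dims: list):
        self.cfg = cfg
        self.feature_dims = list(feature_dims)
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- parameters --------------------------------------------------------

    def _add(self, name: str, t: Tensor) -> Tensor:
        self.params[name] = t
        return t

    def _init_params(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        v = len(self.feature_dims)
        if cfg.variant in _NEEDS_CROSS and v < 2:
            raise ValueError(f"variant {cfg.variant!r} requires >=2 omics layers")

        layers = ([cfg.omics_index] if cfg.variant == "single_graph"
                  else list(range(v)))
        for l in layers:
            W, b = init_affine(rng, self.feature_dims[l], cfg.d_latent)
            self._add(f"W_emb_{l}", W)
            self._add(f"b_emb_{l}", b)

        if cfg.variant in _NEEDS_CROSS:
            for h in range(cfg.n_heads):
                self._add(f"W_Qc_{h}", init_affine(rng, cfg.d_latent, cfg.d_c,
                                                   bias=False,
                                                   gain=cfg.query_gain))
                self._add(f"W_Vc_{h}", init_affine(rng, cfg.d_latent, cfg.d_c,
                                                   bias=False))
            self._add("W1c", init_affine(rng, v * cfg.d_c, cfg.d_head_out,
                                         bias=False))
            d_comb = cfg.n_heads * cfg.d_head_out
        else:
            d_comb = None

        if cfg.variant == "full":
            in_dim = d_comb
        elif cfg.variant == "single_graph":
            in_dim = cfg.d_latent
        elif cfg.variant == "concat_graph":
            in_dim = v * cfg.d_latent
        elif cfg.variant == "cross_attn":
            in_dim = d_comb
        else:
            in_dim = None

        if cfg.variant in _HAS_SAMPLE_ATTENTION:
            self._add("W_Q", init_affine(rng, in_dim, cfg.d_attn, bias=False,
                                         gain=cfg.query_gain))
            self._add("W_V", init_affine(rng, in_dim, cfg.d_attn, bias=False))
            self._add("W1", init_affine(rng, cfg.d_attn, cfg.d_h, bias=False))
            beta_dim = cfg.d_h
        elif cfg.variant == "cross_gcn":
            self._add("W1", init_affine(rng, d_comb, cfg.d_h, bias=False))
            beta_dim = cfg.d_h
        else:  # cross_only
            beta_dim = d_comb
        self._add("beta", init_affine(rng, beta_dim, 1, bias=False))

    def parameters(self) -> list:
        return list(self.params.values())

    # -- forward -----------------------------------------------------------

    def _cross_features(self, X_list) -> Tensor:
        cfg = self.cfg
        Z_list = [
            embed_omics(X, self.params[f"W_emb_{l}"], self.params[f"b_emb_{l}"],
                        cfg.activation)
            for l, X in enumerate(X_list)
        ]
        heads = [
            cross_omics_attention(Z_list, self.params[f"W_Qc_{h}"],
                                  self.params[f"W_Vc_{h}"], cfg.attention_scale)
            for h in range(cfg.n_heads)
        ]
        return combine_heads(heads, self.params["W1c"], cfg.activation)

    def forward(self, X_list, A_hat=None, return_hidden: bool = False):
        """Risk scores (n, 1) for the given preprocessed feature matrices."""
        cfg = self.cfg
        if cfg.variant in _NEEDS_GRAPH and A_hat is None:
            raise ValueError(f"variant {cfg.variant!r} requires a graph")

        if cfg.variant == "single_graph":
            l = cfg.omics_index
            Z = embed_omics(X_list[l], self.params[f"W_emb_{l}"],
                            self.params[f"b_emb_{l}"], cfg.activation)
            Z = structure_biased_attention(Z, A_hat, self.params["W_Q"],
                                           self.params["W_V"], cfg.attention_scale)
            Zh = project_embeddings(Z, self.params["W1"], cfg.activation)
        elif cfg.variant == "concat_graph":
            Z_list = [
                embed_omics(X, self.params[f"W_emb_{l}"], self.params[f"b_emb_{l}"],
                            cfg.activation)
                for l, X in enumerate(X_list)
            ]
            Zcat = concat(Z_list, axis=1)
            Z = structure_biased_attention(Zcat, A_hat, self.params["W_Q"],
                                           self.params["W_V"], cfg.attention_scale)
            Zh = project_embeddings(Z, self.params["W1"], cfg.activation)
        else:
            Zc = self._cross_features(X_list)
            if cfg.variant == "full":
                Z = structure_biased_attention(Zc, A_hat, self.params["W_Q"],
                                               self.params["W_V"],
                                               cfg.attention_scale)
                Zh = project_embeddings(Z, self.params["W1"], cfg.activation)
            elif cfg.variant == "cross_only":
                Zh = Zc
            elif cfg.variant == "cross_gcn":
                Zh = gcn_layer(Zc, A_hat, self.params["W1"], cfg.activation)
            else:  # cross_attn
                Z = plain_attention(Zc, self.params["W_Q"], self.params["W_V"],
                                    cfg.attention_scale)
                Zh = project_embeddings(Z, self.params["W1"], cfg.activation)

        scores = Zh @ self.params["beta"]
        if return_hidden:
            return scores, Zh
        return scores


def build_model(variant: str, feature_dims: list, **cfg_kwargs) -> Model:
    """Construct an untrained model of the given variant."""
    return Model(ModelConfig(variant=variant, **cfg_kwargs), feature_dims)


def fit(model: Model, X_list, surv: SurvivalTable, graph: FusedGraph | None = None,
        epochs: int | None = None) -> list:
    """Minimise the Cox partial likelihood with full-batch Adam.

    Returns the per-epoch loss trace.  Aborts on a non-finite loss.
    """
    cfg = model.cfg
    if surv.n_events < 1:
        raise ValueError("training requires at least one observed event")
    X_list = [np.asarray(X.values if isinstance(X, OmicsMatrix) else X, float)
              for X in X_list]
    A_hat = graph.conv_matrix if graph is not None else None
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    trace = []
    n_epochs = cfg.epochs if epochs is None else epochs
    for epoch in range(n_epochs):
        opt.zero_grad()
        scores = model.forward(X_list, A_hat)
        loss = cox_partial_loss_tensor(scores, surv, strict=cfg.strict_risk_set)
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        trace.append(val)
        loss.backward()
        opt.step()
    return trace


# ---------------------------------------------------------------------------
# end-to-end pipeline with inductive test-sample attachment
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """A trained model together with everything needed to score new samples."""

    cfg: ModelConfig
    model: Model
    preprocessors: list
    graph: FusedGraph | None
    X_train: list
    surv_train: SurvivalTable
    loss_trace: list = field(default_factory=list)
    head: CoxHead | None = None

    def _graph_layers(self, X_list):
        if self.cfg.variant == "single_graph":
            return [X_list[self.cfg.omics_index]]
        return X_list

    def predict_risk(self, omics_test, return_hidden: bool = False):
        """Risk scores for held-out samples (inductive graph attachment)."""
        X_test = [pp.transform(m).values
                  for pp, m in zip(self.preprocessors, omics_test)]
        n_tr = self.X_train[0].shape[0]
        X_comb = [np.vstack([tr, te]) for tr, te in zip(self.X_train, X_test)]
        if self.graph is not None:
            comb = attach_test_samples(self.graph, self._graph_layers(self.X_train),
                                       self._graph_layers(X_test))
            A_hat = comb.conv_matrix
        else:
            A_hat = None
        scores, Zh = self.model.forward(X_comb, A_hat, return_hidden=True)
        s = scores.data.ravel()[n_tr:]
        if return_hidden:
            return s, Zh.data[n_tr:]
        return s

    def training_scores(self, return_hidden: bool = False):
        A_hat = self.graph.conv_matrix if self.graph is not None else None
        scores, Zh = self.model.forward(self.X_train, A_hat, return_hidden=True)
        if return_hidden:
            return scores.data.ravel(), Zh.data
        return scores.data.ravel()

    # -- serialisation -----------------------------------------------------

    def save(self, path) -> None:
        """Write the pipeline to one ``.npz`` archive (exact round-trip)."""
        arrays = {}
        meta = {
            "cfg": dataclasses.asdict(self.cfg),
            "feature_dims": self.model.feature_dims,
            "n_omics": len(self.X_train),
            "has_graph": self.graph is not None,
            "loss_trace": self.loss_trace,
            "param_names": sorted(self.params_arrays(arrays)),
            "pp": [],
        }
        for i, pp in enumerate(self.preprocessors):
            meta["pp"].append({
                "missing_threshold": pp.missing_threshold,
                "top_k": pp.top_k,
                "log_transform": bool(pp.log_transform),
                "feature_ids": pp.feature_ids,
            })
            for attr in ("keep_idx", "medians", "means", "sds"):
                arrays[f"pp{i}_{attr}"] = np.asarray(getattr(pp, attr))
        for i, X in enumerate(self.X_train):
            arrays[f"Xtr_{i}"] = X
        arrays["surv_time"] = self.surv_train.time
        arrays["surv_event"] = self.surv_train.event
        if self.graph is not None:
            g = self.graph
            arrays["g_fused"] = g.fused_adjacency
            arrays["g_conv"] = g.conv_matrix
            for i, a in enumerate(g.per_omics_adjacency):
                arrays[f"g_adj_{i}"] = a
            meta["graph"] = {"K": g.K, "mu": list(g.mu),
                             "delta_sq": list(g.delta_sq),
                             "n_layers": len(g.per_omics_adjacency)}
        arrays["_meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def params_arrays(self, arrays: dict) -> list:
        names = []
        for name, p in self.model.params.items():
            arrays[f"param_{name}"] = p.data
            names.append(name)
        return names

    @classmethod
    def load(cls, path) -> "FittedPipeline":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["_meta"].tobytes()).decode())
            cfg = ModelConfig(**meta["cfg"])
            model = Model(cfg, meta["feature_dims"])
            for name in meta["param_names"]:
                model.params[name].data = z[f"param_{name}"].copy()
            pps = []
            for i, info in enumerate(meta["pp"]):
                pp = Preprocessor(info["missing_threshold"], info["top_k"])
                pp.keep_idx = z[f"pp{i}_keep_idx"].copy()
                pp.medians = z[f"pp{i}_medians"].copy()
                pp.means = z[f"pp{i}_means"].copy()
                pp.sds = z[f"pp{i}_sds"].copy()
                pp.log_transform = info["log_transform"]
                pp.feature_ids = info["feature_ids"]
                pps.append(pp)
            X_train = [z[f"Xtr_{i}"].copy() for i in range(meta["n_omics"])]
            surv = SurvivalTable(z["surv_time"].copy(), z["surv_event"].copy())
            graph = None
            if meta["has_graph"]:
                gi = meta["graph"]
                graph = FusedGraph(
                    [z[f"g_adj_{i}"].copy() for i in range(gi["n_layers"])],
                    z["g_fused"].copy(), z["g_conv"].copy(),
                    gi["K"], gi["mu"], gi["delta_sq"],
                )
        pipe = cls(cfg, model, pps, graph, X_train, surv,
                   loss_trace=meta["loss_trace"])
        pipe.head = CoxHead(model.params["beta"].data.ravel().copy())
        pipe.head.baseline = breslow_baseline(pipe.training_scores(), surv)
        return pipe


def fit_pipeline(omics_list, surv: SurvivalTable, cfg: ModelConfig) -> FittedPipeline:
    """Preprocess, build the graph, train and fit the baseline hazard."""
    pps = [Preprocessor(top_k=cfg.top_k).fit(m) for m in omics_list]
    X_list = [pp.transform(m).values for pp, m in zip(pps, omics_list)]

    graph = None
    if cfg.variant in _NEEDS_GRAPH:
        if cfg.variant == "single_graph":
            layers = [X_list[cfg.omics_index]]
            mus = [cfg.mus[cfg.omics_index] if cfg.mus
                   else default_mu(cfg.omics_index)]
        else:
            layers = X_list
            mus = cfg.mus
        graph = build_fused_graph(layers, K=min(cfg.K, len(surv) - 1), mus=mus)

    model = Model(cfg, [X.shape[1] for X in X_list])
    trace = fit(model, X_list, surv, graph)
    pipe = FittedPipeline(cfg, model, pps, graph, X_list, surv, trace)
    pipe.head = CoxHead(model.params["beta"].data.ravel().copy())
    pipe.head.baseline = breslow_baseline(pipe.training_scores(), surv)
    return pipe


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def _split_with_events(rng, surv: SurvivalTable, train_frac: float,
                       max_redraws: int = 20):
    n = len(surv)
    n_tr = int(round(train_frac * n))
    for attempt in range(max_redraws):
        perm = rng.permutation(n)
        tr, te = perm[:n_tr], perm[n_tr:]
        if surv.event[tr].sum() >= 1 and surv.event[te].sum() >= 1:
            if attempt:
                warnings.warn(f"redrew split {attempt} time(s) to obtain events")
            return tr, te
    raise RuntimeError("could not draw a split with events in both subsets")


def repeated_holdout(omics_list, surv: SurvivalTable, cfg: ModelConfig,
                     n_repeats: int = 50, train_frac: float = 0.8,
                     seed: int | None = None):
    """Random 80/20 holdout, repeated; returns per-repeat results + summary.

    Each repeat refits preprocessing and the graph on its training split only
    and scores the held-out fifth inductively.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    results = []
    for rep in range(n_repeats):
        tr, te = _split_with_events(rng, surv, train_frac)
        rep_cfg = dataclasses.replace(cfg, seed=int(rng.integers(2**31)))
        pipe = fit_pipeline([m.subset(tr) for m in omics_list],
                            surv.subset(tr), rep_cfg)
        s_test = pipe.predict_risk([m.subset(te) for m in omics_list])
        surv_te = surv.subset(te)
        res = EvalResult()
        try:
            res.c_index, res.n_comparable_pairs = concordance_index(s_test, surv_te)
            res.auc, res.n_auc_pairs = time_dependent_auc(s_test, surv_te)
        except ValueError as err:
            warnings.warn(f"repeat {rep}: {err}")
        results.append(res)
    cs = np.array([r.c_index for r in results])
    aucs = np.array([r.auc for r in results])
    summary = {
        "c_index_mean": float(np.nanmean(cs)),
        "c_index_sd": float(np.nanstd(cs)),
        "auc_mean": float(np.nanmean(aucs)),
        "auc_sd": float(np.nanstd(aucs)),
        "n_repeats": n_repeats,
    }
    return results, summary


def select_K(omics_list, surv: SurvivalTable, grid, cfg: ModelConfig,
             folds: int = 3):
    """Choose the KNN neighbourhood size by inner cross-validation.

    Returns the K from ``grid`` with the best mean validation C-index;
    exact ties go to the smaller K.
    """
    from sklearn.model_selection import KFold

    grid = sorted(grid)
    if not grid:
        raise ValueError("empty K grid")
    if len(grid) == 1:
        return grid[0], {grid[0]: np.nan}
    best_K, best_c = None, -np.inf
    curve = {}
    for K in grid:
        cs = []
        splitter = KFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
        for tr, te in splitter.split(np.arange(len(surv))):
            if surv.event[tr].sum() < 1 or surv.event[te].sum() < 1:
                continue
            rep_cfg = dataclasses.replace(cfg, K=K)
            pipe = fit_pipeline([m.subset(tr) for m in omics_list],
                                surv.subset(tr), rep_cfg)
            s = pipe.predict_risk([m.subset(te) for m in omics_list])
            try:
                c, _ = concordance_index(s, surv.subset(te))
                cs.append(c)
            except ValueError:
                continue
        mean_c = float(np.mean(cs)) if cs else -np.inf
        curve[K] = mean_c
        if mean_c > best_c:  # strict: ties keep the earlier (smaller) K
            best_K, best_c = K, mean_c
    return best_K, curve


def feature_correlation_analysis(X_raw, Zh, top_m: int = 10,
                                 feature_ids=None) -> pd.DataFrame:
    """Pearson correlation of raw features with each hidden embedding column.

    Returns a tidy table (hidden_node, rank, feature_id, r) with the top_m
    features per hidden node ranked by \\|r\\|; zero-variance hidden columns
    are skipped with a warning.
    """
    if isinstance(X_raw, OmicsMatrix):
        feature_ids = feature_ids or X_raw.feature_ids
        X = X_raw.values
    else:
        X = np.asarray(X_raw, float)
        if feature_ids is None:
            feature_ids = [f"f{j}" for j in range(X.shape[1])]
    Zh = np.asarray(Zh, float)
    if X.shape[0] != Zh.shape[0]:
        raise ValueError("raw features and hidden embeddings must share rows")

    Xc = X - X.mean(axis=0)
    x_sd = X.std(axis=0)
    rows = []
    for h in range(Zh.shape[1]):
        z = Zh[:, h]
        if z.std() == 0:
            warnings.warn(f"hidden node {h} has zero variance; skipped")
            continue
        zc = z - z.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ zc) / (len(z) * x_sd * z.std())
        r = np.where(x_sd > 0, r, 0.0)
        top = np.argsort(-np.abs(r), kind="stable")[:top_m]
        for rank, j in enumerate(top):
            rows.append({"hidden_node": h, "rank": rank + 1,
                         "feature_id": feature_ids[j], "r": float(r[j])})
    return pd.DataFrame(rows, columns=["hidden_node", "rank", "feature_id", "r"])
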