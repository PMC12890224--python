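"""Inter-omics and inter-sample attention blocks.

Two attention mechanisms operate in sequence:

*Inter-omics attention* acts within each sample, across its omics layers.
Each preprocessed layer is embedded by a single affine layer into a shared
latent width, then a shared query/value projection (one matrix pair per
head, the same pair for every layer — keys coincide with queries to halve
the parameter count) produces, for each sample i and source layer u1,

    alpha_i^{u1,u2} = <q_i^{u1}, q_i^{u2}> / d_c      (softmax over u2)
    z_i^{u1,c}      = sum_{u2} alpha-hat_i^{u1,u2} v_i^{u2},

stacked over u1 and, across heads, compressed by one shared linear map and
concatenated.  The divisor is the raw projection width d_c by default (a
``sqrt_dim`` switch gives the conventional scaling).

*Inter-sample attention* acts across samples on the combined cross-omics
features Z^c.  Plain attention is row-softmax(Q Q^T / d) V.  The
structure-biased form multiplies each attention kernel entry by the fused
graph's convolution matrix entry before normalising, restricting support to
graph neighbourhoods (A_hat is zero elsewhere, positive on the diagonal):

    alpha-hat(i,j) = exp(q_i^T q_j / d) * A_hat(i,j)
                     / sum_{j' in N_i} exp(q_i^T q_j' / d) * A_hat(i,j').

A GCN-style layer f(A_hat Z^c W) serves as the fixed-weight aggregation
ablation.

All functions operate on autodiff :class:`~survformer._autodiff.Tensor`
objects so the whole model is trainable end-to-end; plain numpy arrays are
accepted and wrapped, so each operation is also directly inspectable.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, softmax_rows

__all__ = [
    "init_affine",
    "embed_omics",
    "cross_omics_attention",
    "combine_heads",
    "structure_biased_attention",
    "plain_attention",
    "project_embeddings",
    "gcn_layer",
    "ACTIVATIONS",
]

ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "linear": lambda t: t,
}


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def init_affine(rng: np.random.Generator, fan_in: int, fan_out: int,
                bias: bool = True, gain: float = 1.0):
    """Scaled uniform fan-in initialisation: U(-g/sqrt(fan_in), g/sqrt(fan_in)).

    Query projections use gain > 1 so that attention logits (inner products
    divided by the full width d) start at order one rather than near zero,
    which lets the softmax sharpen during training instead of staying
    uniform.
    """
    bound = gain / np.sqrt(fan_in)
    W = Tensor(rng.uniform(-bound, bound, size=(fan_in, fan_out)), requires_grad=True)
    if not bias:
        return W
    b = Tensor(rng.uniform(-bound, bound, size=(1, fan_out)), requires_grad=True)
    return W, b


# ---------------------------------------------------------------------------
# inter-omics block
# ---------------------------------------------------------------------------

def embed_omics(X, W, b=None, activation: str = "relu") -> Tensor:
    """Single affine embedding Z = f(X W + b) of one preprocessed omics layer."""
    X, W = _lift(X), _lift(W)
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match embedding input {W.shape[0]}"
        )
    Z = X @ W
    if b is not None:
        Z = Z + _lift(b)
    return ACTIVATIONS[activation](Z)


def _attention_divisor(d_c: int, attention_scale: str) -> float:
    if attention_scale == "dim":
        return float(d_c)
    if attention_scale == "sqrt_dim":
        return float(np.sqrt(d_c))
    raise ValueError(f"unknown attention_scale {attention_scale!r}")


def cross_omics_attention(Z_list, W_Qc, W_Vc, attention_scale: str = "dim",
                          return_weights: bool = False):
    """One head of within-sample, cross-omics attention.

    Parameters
    ----------
    Z_list : list of (n, d_latent) latent layers, one per omics (>= 2).
    W_Qc, W_Vc : shared (d_latent, d_c) query and value projections.

    Returns the head output of shape (n, v * d_c) — the per-source-layer
    contextualised features stacked along the feature axis — and, if
    requested, the (n, v, v) row-stochastic attention array.
    """
    if len(Z_list) < 2:
        raise ValueError("cross-omics attention requires >=2 layers")
    Z_list = [_lift(Z) for Z in Z_list]
    W_Qc, W_Vc = _lift(W_Qc), _lift(W_Vc)
    d_c = W_Qc.shape[1]
    div = _attention_divisor(d_c, attention_scale)
    Q = [Z @ W_Qc for Z in Z_list]
    V = [Z @ W_Vc for Z in Z_list]

    outputs, weights = [], []
    for u1 in range(len(Z_list)):
        scores = [
            (Q[u1] * Q[u2]).sum(axis=1, keepdims=True) / div
            for u2 in range(len(Z_list))
        ]
        alpha = softmax_rows(concat(scores, axis=1))  # (n, v)
        zc = None
        for u2 in range(len(Z_list)):
            term = alpha.cols(u2, u2 + 1) * V[u2]
            zc = term if zc is None else zc + term
        outputs.append(zc)
        weights.append(alpha.data)
    head = concat(outputs, axis=1)
    if return_weights:
        return head, np.stack(weights, axis=1)  # (n, v source, v target)
    return head


def combine_heads(heads, W1c, activation: str = "relu") -> Tensor:
    """Compress each head with the shared map W1c and concatenate them."""
    heads = [_lift(h) for h in heads]
    W1c = _lift(W1c)
    shape = heads[0].shape
    for h in heads:
        if h.shape != shape:
            raise ValueError("head shape mismatch")
    act = ACTIVATIONS[activation]
    parts = [act(h @ W1c) for h in heads]
    return parts[0] if len(parts) == 1 else concat(parts, axis=1)


# ---------------------------------------------------------------------------
# inter-sample block
# ---------------------------------------------------------------------------

def structure_biased_attention(Zc, A_hat, W_Q, W_V, attention_scale: str = "dim",
                               return_weights: bool = False):
    """Attention kernel multiplied entrywise by the graph convolution matrix.

    Support is restricted to the fused-graph neighbourhood of each sample
    (entries where A_hat is zero contribute nothing); the diagonal of A_hat
    is strictly positive so every row normalises.
    """
    Zc, W_Q, W_V = _lift(Zc), _lift(W_Q), _lift(W_V)
    A_hat = np.asarray(A_hat.data if isinstance(A_hat, Tensor) else A_hat, float)
    Q = Zc @ W_Q
    V = Zc @ W_V
    d = _attention_divisor(W_Q.shape[1], attention_scale)
    S = (Q @ Q.T) / d
    if not np.all(np.isfinite(S.data)):
        raise FloatingPointError("non-finite attention scores")
    # mask scores outside the neighbourhood before exponentiating, and shift
    # by the (detached) row max over the support: the result is exactly local
    # to N_i and numerically safe for arbitrarily large scores
    support = (A_hat > 0).astype(float)
    masked = np.where(support > 0, S.data, -np.inf)
    shift = Tensor(masked.max(axis=1, keepdims=True))
    S_eff = S * Tensor(support) - Tensor(1e30 * (1.0 - support))
    P = (S_eff - shift).exp() * Tensor(A_hat)
    alpha = P / P.sum(axis=1, keepdims=True)
    Z = alpha @ V
    if return_weights:
        return Z, alpha.data
    return Z


def plain_attention(Zc, W_Q, W_V, attention_scale: str = "dim",
                    return_weights: bool = False):
    """Unbiased attention over all samples: row-softmax(Q Q^T / d) V."""
    Zc, W_Q, W_V = _lift(Zc), _lift(W_Q), _lift(W_V)
    Q = Zc @ W_Q
    V = Zc @ W_V
    d = _attention_divisor(W_Q.shape[1], attention_scale)
    alpha = softmax_rows((Q @ Q.T) / d)
    Z = alpha @ V
    if return_weights:
        return Z, alpha.data
    return Z


def project_embeddings(Z, W1, activation: str = "relu") -> Tensor:
    """Final per-sample projection z_i^h = f(z_i W1)."""
    Z, W1 = _lift(Z), _lift(W1)
    if Z.shape[1] != W1.shape[0]:
        raise ValueError(f"width mismatch: {Z.shape[1]} vs {W1.shape[0]}")
    return ACTIVATIONS[activation](Z @ W1)


def gcn_layer(Zc, A_hat, W1, activation: str = "relu") -> Tensor:
    """Fixed-weight graph aggregation Zh = f(A_hat Z^c W1) (attention ablated)."""
    Zc, W1 = _lift(Zc), _lift(W1)
    A_hat = np.asarray(A_hat.data if isinstance(A_hat, Tensor) else A_hat, float)
    return ACTIVATIONS[activation]((Tensor(A_hat) @ Zc) @ W1)
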