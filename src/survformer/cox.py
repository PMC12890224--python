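"""Cox proportional-hazards head: partial-likelihood loss, Breslow baseline
hazard, and survival-curve prediction.

The training objective is the negative log partial likelihood

    L(beta) = - sum_{i: delta_i = 1} [ s_i - log sum_{j in R(O_i)} exp(s_j) ],

with s_i the model's risk score and R(t) the risk set.  By default R(t) =
{j : O_j >= t} (the standard inclusive risk set, Breslow handling of ties);
``strict=True`` uses R(t) = {j : O_j > t}, in which case events whose risk
set is empty (in particular the last event) are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .io import SurvivalTable

__all__ = [
    "cox_partial_loss",
    "cox_partial_loss_tensor",
    "breslow_baseline",
    "BreslowBaseline",
    "CoxHead",
    "predict",
]


def _risk_mask(time: np.ndarray, event: np.ndarray, strict: bool):
    """Boolean (n_events, n) mask: row e selects the risk set of event e."""
    ev_idx = np.flatnonzero(event == 1)
    if strict:
        mask = time[None, :] > time[ev_idx, None]
        keep = mask.any(axis=1)
        ev_idx, mask = ev_idx[keep], mask[keep]
    else:
        mask = time[None, :] >= time[ev_idx, None]
    return ev_idx, mask


def cox_partial_loss_tensor(scores: Tensor, surv: SurvivalTable,
                            strict: bool = False) -> Tensor:
    """Differentiable negative log partial likelihood (sum over events)."""
    n = len(surv)
    if scores.data.size != n:
        raise ValueError("scores length does not match survival table")
    if not np.all(np.isfinite(scores.data)):
        raise ValueError("non-finite risk scores")

    ev_idx, mask = _risk_mask(surv.time, surv.event, strict)
    if len(ev_idx) == 0:
        warnings.warn("no events in batch")
        return Tensor(0.0)

    col2 = scores if scores.data.ndim == 2 else _reshape_col(scores)
    shift = Tensor(col2.data.max())  # detached; exact for the log-sum-exp
    e = (col2 - shift).exp()  # (n, 1)
    risk_sums = Tensor(mask.astype(float)) @ e  # (n_events, 1)
    lse = risk_sums.log() + shift
    selector = np.zeros((len(ev_idx), n))
    selector[np.arange(len(ev_idx)), ev_idx] = 1.0
    s_events = Tensor(selector) @ col2
    return -(s_events - lse).sum()


def _reshape_col(t: Tensor) -> Tensor:
    """View a 1-d tensor as a column via an identity matmul (keeps gradients)."""
    n = t.data.size

    def bwd(g):
        if t.requires_grad:
            t._accum(g.reshape(t.data.shape))

    return Tensor(t.data.reshape(n, 1), parents=(t,), backward=bwd)


def cox_partial_loss(scores, surv: SurvivalTable, strict: bool = False) -> float:
    """Negative log partial likelihood of plain numpy risk scores."""
    t = Tensor(np.asarray(scores, dtype=float).reshape(-1, 1))
    return float(cox_partial_loss_tensor(t, surv, strict=strict).data)


@dataclass
class BreslowBaseline:
    """Right-continuous step estimate of the cumulative baseline hazard."""

    times: np.ndarray        # distinct event times, ascending
    increments: np.ndarray   # d(t) / sum_{j in R(t)} exp(s_j)

    @property
    def cum_hazard(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def __call__(self, t) -> np.ndarray:
        """Cumulative hazard Lambda_0(t), 0 before the first event time."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right")
        cum = np.concatenate([[0.0], self.cum_hazard])
        out = cum[idx]
        return out if np.ndim(t) else float(out[0])


def breslow_baseline(scores, surv: SurvivalTable) -> BreslowBaseline:
    """Breslow estimator: increment d(t) / sum_{O_j >= t} exp(s_j) per event time."""
    s = np.asarray(scores, dtype=float).ravel()
    ev = surv.event == 1
    if not ev.any():
        warnings.warn("no events in batch")
        return BreslowBaseline(np.array([]), np.array([]))
    times = np.unique(surv.time[ev])
    exp_s = np.exp(s - s.max())
    scale = np.exp(s.max())
    increments = np.empty_like(times)
    for k, t in enumerate(times):
        d = int(((surv.time == t) & ev).sum())
        denom = exp_s[surv.time >= t].sum() * scale
        increments[k] = d / denom
    return BreslowBaseline(times, increments)


@dataclass
class CoxHead:
    """Fitted linear risk map plus an optional baseline hazard."""

    beta: np.ndarray
    baseline: BreslowBaseline | None = None

    def fit_baseline(self, Zh, surv: SurvivalTable) -> "CoxHead":
        self.baseline = breslow_baseline(self.scores(Zh), surv)
        return self

    def scores(self, Zh) -> np.ndarray:
        return np.asarray(Zh, dtype=float) @ self.beta.ravel()


def predict(Zh, head: CoxHead, times=None):
    """Risk scores and, if a baseline is fitted, survival curves S_i(t).

    Returns ``scores`` when ``times`` is None, else ``(scores, S)`` with S of
    shape (n_samples, n_times), S_i(t) = exp(-Lambda_0(t) exp(score_i)).
    """
    scores = head.scores(Zh)
    if times is None:
        return scores
    if head.baseline is None:
        raise RuntimeError("baseline hazard not fitted; risk scores only")
    cum = head.baseline(np.asarray(times, dtype=float))
    S = np.exp(-np.outer(np.exp(scores), cum))
    return scores, S
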