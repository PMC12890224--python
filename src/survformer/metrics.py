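"""Evaluation metrics for right-censored risk predictions.

*Concordance index* — over every pair of samples in which the one with the
shorter observed time experienced the event (pairs whose shorter time is
censored, pairs of two censored samples, and pairs with tied times are
excluded), the fraction where the shorter-lived sample received the higher
risk score; tied scores count 1/2.

*Time-dependent AUC* — pooled over the set Y of distinct observed event
times t, the fraction of sample pairs (i past the time, O_i < t; j beyond
it, O_j > t) that are ranked correctly by risk score:

    AUC = (1 / N_num) * sum_{t in Y} sum_{i: O_i < t} sum_{j: O_j > t}
          I(score_i > score_j).

As written the outer sum does not restrict i to event cases; that reading is
the default, and ``cases="events_only"`` gives the conventional
cumulative/dynamic variant.

*Risk stratification* — median split of risk scores into high/low groups,
Kaplan–Meier curves per group and a two-sample log-rank test (via
lifelines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import SurvivalTable

__all__ = [
    "EvalResult",
    "concordance_index",
    "time_dependent_auc",
    "km_logrank",
]


@dataclass
class EvalResult:
    """Per-evaluation summary: discrimination metrics and risk groups."""

    c_index: float = np.nan
    auc: float = np.nan
    n_comparable_pairs: int = 0
    n_auc_pairs: int = 0
    logrank_stat: float = np.nan
    logrank_p: float = np.nan
    group_labels: np.ndarray | None = None
    km_curves: dict = field(default_factory=dict)


def _check_scores(scores, surv: SurvivalTable) -> np.ndarray:
    s = np.asarray(scores, dtype=float).ravel()
    if len(s) != len(surv):
        raise ValueError("scores length does not match survival table")
    return s


def concordance_index(scores, surv: SurvivalTable):
    """Concordance index and the number of comparable pairs.

    Vectorised over all ordered pairs: pair (i, j) is comparable when
    O_i < O_j and delta_i = 1.  Concordant if score_i > score_j, tied scores
    count 0.5.
    """
    s = _check_scores(scores, surv)
    O, d = surv.time, surv.event
    shorter_event = (O[:, None] < O[None, :]) & (d[:, None] == 1)
    n_pairs = int(shorter_event.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs: concordance index undefined")
    conc = (s[:, None] > s[None, :]) + 0.5 * (s[:, None] == s[None, :])
    return float((conc * shorter_event).sum() / n_pairs), n_pairs


def time_dependent_auc(scores, surv: SurvivalTable, cases: str = "all"):
    """Time-pooled ranking accuracy and the number of enumerated pairs.

    For each distinct event time t, every (i, j) with O_i < t < O_j is a
    pair; a pair occurring at several event times is counted once per time.
    ``cases="events_only"`` restricts i to samples with an observed event.
    """
    if cases not in ("all", "events_only"):
        raise ValueError(f"unknown cases mode {cases!r}")
    s = _check_scores(scores, surv)
    O, d = surv.time, surv.event
    Y = np.unique(O[d == 1])
    if len(Y) == 0:
        raise ValueError("no event times: AUC undefined")
    # pair (i, j) is enumerated once for each t in Y with O_i < t < O_j
    counts = (
        np.searchsorted(Y, O, side="left")[None, :]   # #\{t <= O_j\} -> t < O_j uses 'left'
        - np.searchsorted(Y, O, side="right")[:, None]
    )
    counts = np.maximum(counts, 0).astype(float)  # (i, j): #\{t in Y: O_i < t < O_j\}
    if cases == "events_only":
        counts *= (d[:, None] == 1)
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise ValueError("no valid pairs: AUC undefined")
    correct = (s[:, None] > s[None, :]) + 0.5 * (s[:, None] == s[None, :])
    return float((correct * counts).sum() / n_pairs), n_pairs


def km_logrank(scores, surv: SurvivalTable, split: str = "median") -> EvalResult:
    """Median-split risk stratification with K-M curves and a log-rank test.

    Samples with score strictly above the median form the high-risk group.
    """
    if split != "median":
        raise ValueError(f"unknown split rule {split!r}")
    s = _check_scores(scores, surv)
    high = s > np.median(s)
    if high.all() or not high.any():
        raise ValueError("median split produced an empty risk group")

    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(surv.time[mask], surv.event[mask])
        curves[name] = km
    lr = logrank_test(
        surv.time[high], surv.time[~high], surv.event[high], surv.event[~high]
    )
    res = EvalResult(
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        group_labels=np.where(high, "high", "low"),
        km_curves=curves,
    )
    try:
        res.c_index, res.n_comparable_pairs = concordance_index(s, surv)
    except ValueError:
        pass
    return res
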