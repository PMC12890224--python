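"""Reading, alignment and preprocessing of omics matrices and survival tables.

Input layout: each omics layer is a CSV/TSV matrix with a header row of
feature identifiers and the first column holding sample identifiers; the
survival table has columns ``sample_id, time, event`` with ``event`` being 1
for an observed death and 0 for right censoring.

The preprocessing pipeline mirrors standard expression workflows: drop
features with too many missing values, median-impute the rest, log-transform
nonnegative data, keep the highest-variance features, and standardise each
kept feature to mean 0 / sd 1.  For train/test protocols the pipeline is fit
on training samples only and applied to held-out samples via
:class:`Preprocessor`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SurvivalTable",
    "load_dataset",
    "Preprocessor",
    "preprocess_omics",
    "write_omics",
    "write_survival",
]

_MISSING_TOKENS = {"", "na", "nan"}


@dataclass
class OmicsMatrix:
    """One omics layer: an n-samples x p-features real matrix with identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_name: str = "omics"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"{self.omics_name}: value matrix {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.omics_name}: duplicate sample identifiers")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "OmicsMatrix":
        idx = np.asarray(idx)
        return OmicsMatrix(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.omics_name,
        )


@dataclass
class SurvivalTable:
    """Observed time O_i >= 0 and event indicator delta_i in {0,1} per sample."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if np.any(self.time < 0):
            raise ValueError("observed times must be nonnegative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        self.event = self.event.astype(int)
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(len(self.time))]

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalTable":
        idx = np.asarray(idx)
        return SurvivalTable(
            self.time[idx], self.event[idx], [self.sample_ids[i] for i in idx]
        )


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)


def _is_missing_token(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True
    return str(v).strip().lower() in _MISSING_TOKENS


def _to_float(df: pd.DataFrame, path) -> np.ndarray:
    """Parse matrix cells, mapping missing tokens to NaN; report bad cells."""
    raw = df.to_numpy(dtype=object)
    missing = np.vectorize(_is_missing_token, otypes=[bool])(raw)
    parsed = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(parsed) & ~missing
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: non-numeric value {raw[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    parsed[missing] = np.nan
    return parsed


def load_dataset(omics_paths, survival_path):
    """Load omics matrices and a survival table, aligned on shared sample IDs.

    All matrices and the survival table are restricted to the intersection of
    their sample identifiers, in the survival table's order.
    """
    surv_df = pd.read_csv(survival_path, sep=None, engine="python")
    required = {"sample_id", "time", "event"}
    if not required.issubset(surv_df.columns):
        raise ValueError(f"{survival_path}: expected columns {sorted(required)}")
    surv_df["sample_id"] = surv_df["sample_id"].astype(str)

    matrices = []
    for path in omics_paths:
        df = _read_table(path)
        name = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
        matrices.append(
            OmicsMatrix(_to_float(df, path), list(df.index.astype(str)),
                        list(df.columns.astype(str)), name)
        )

    shared = set(surv_df["sample_id"])
    for m in matrices:
        shared &= set(m.sample_ids)
    if not shared:
        raise ValueError("no sample identifiers shared by all inputs")

    order = [s for s in surv_df["sample_id"] if s in shared]
    surv_df = surv_df.set_index("sample_id").loc[order]
    surv = SurvivalTable(
        surv_df["time"].astype(float).to_numpy(),
        surv_df["event"].astype(float).to_numpy(),
        order,
    )
    aligned = []
    for m in matrices:
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        aligned.append(m.subset([pos[s] for s in order]))
    return aligned, surv


@dataclass
class Preprocessor:
    """Preprocessing pipeline fit on one cohort and applicable to another.

    Stages, in order: (1) drop features whose missing fraction exceeds
    ``missing_threshold``; (2) median-impute remaining missing values
    (medians over observed training values); (3) log2(x+1) if the training
    matrix is nonnegative, otherwise skipped with a warning; (4) drop
    zero-variance features, keep the ``top_k`` highest-variance features
    (ties broken by original column order); (5) standardise to mean 0, sd 1
    using training statistics.
    """

    missing_threshold: float = 0.10
    top_k: int | None = None
    keep_idx: np.ndarray | None = None
    medians: np.ndarray | None = None
    log_transform: bool = True
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    feature_ids: list[str] | None = None

    def fit(self, m: OmicsMatrix) -> "Preprocessor":
        X = m.values.copy()
        missing_frac = np.isnan(X).mean(axis=0)
        stage1 = np.flatnonzero(missing_frac <= self.missing_threshold)
        X = X[:, stage1]

        medians = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), medians, X)

        self.log_transform = not np.any(X < 0)
        if self.log_transform:
            X = np.log2(X + 1.0)
        else:
            warnings.warn(
                f"{m.omics_name}: negative values present, skipping log transform"
            )

        variances = X.var(axis=0)
        nonconst = np.flatnonzero(variances > 0)
        top_k = self.top_k if self.top_k is not None else len(nonconst)
        if len(nonconst) < top_k:
            warnings.warn(
                f"{m.omics_name}: only {len(nonconst)} features survive filtering "
                f"(requested top {top_k}); keeping all survivors"
            )
            top_k = len(nonconst)
        # stable sort on descending variance keeps original order among ties
        order = nonconst[np.argsort(-variances[nonconst], kind="stable")[:top_k]]
        order = np.sort(order)  # preserve original column order of kept features

        self.keep_idx = stage1[order]
        self.medians = medians[order]
        kept = X[:, order]
        self.means = kept.mean(axis=0)
        self.sds = kept.std(axis=0)
        self.feature_ids = [m.feature_ids[i] for i in self.keep_idx]
        return self

    def transform(self, m: OmicsMatrix) -> OmicsMatrix:
        if self.keep_idx is None:
            raise RuntimeError("Preprocessor not fitted")
        X = m.values[:, self.keep_idx].copy()
        X = np.where(np.isnan(X), self.medians, X)
        if self.log_transform:
            X = np.log2(X + 1.0)
        X = (X - self.means) / self.sds
        return OmicsMatrix(X, list(m.sample_ids), list(self.feature_ids), m.omics_name)

    def fit_transform(self, m: OmicsMatrix) -> OmicsMatrix:
        return self.fit(m).transform(m)


def preprocess_omics(m: OmicsMatrix, missing_threshold: float = 0.10,
                     top_k: int | None = None) -> OmicsMatrix:
    """One-shot preprocessing (fit and apply on the same cohort)."""
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    return Preprocessor(missing_threshold, top_k).fit_transform(m)


def write_omics(m: OmicsMatrix, path, sep: str = ",") -> None:
    pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids).to_csv(
        path, sep=sep, index_label="sample_id"
    )


def write_survival(s: SurvivalTable, path, sep: str = ",") -> None:
    pd.DataFrame(
        {"sample_id": s.sample_ids, "time": s.time, "event": s.event}
    ).to_csv(path, sep=sep, index=False)
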