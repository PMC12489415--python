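"""Chained-equations multiple imputation with predictive mean matching.

Each variable with missing values is imputed conditionally on all other
variables, cycling until the configured number of iterations, and the whole
procedure repeats to give m completed datasets.  Ordinal and numeric
variables use predictive mean matching (PMM): a linear model predicts the
missing entry and the imputed value is the observed value of one of the k
donors with the closest predictions, drawn uniformly, so imputations always
lie in the observed support.  Unordered categoricals use a multinomial
(polytomous) regression draw.  Instrument totals are never imputed
directly; they are recomputed from items in every completed dataset
(passive imputation).  The m datasets are then consolidated into a single
analysis dataset by taking, for each originally missing cell, the
across-dataset mode with ties broken toward the smallest code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instruments import GAD7_ITEMS, GAD7_ITEMS_T2, PHQ9_ITEMS, PHQ9_ITEMS_T2

#: columns never used as predictors nor imputed
ID_COLUMNS = ("student_id",)

#: derived columns (recomputed passively, excluded from chained equations)
TOTAL_COLUMNS = (
    "PHQ9_TOTAL_1", "GAD7_TOTAL_1", "PHQ2_TOTAL_1", "GAD2_TOTAL_1",
    "PHQ9_TOTAL_2", "GAD7_TOTAL_2",
)


@dataclass
class ImputationSpec:
    """Configuration of the chained-equations procedure."""

    m: int = 10
    iterations: int = 10
    k: int = 5
    methods: dict[str, str] = field(default_factory=dict)  # per-variable override
    categorical: tuple[str, ...] = ("PROGRAM", "SEX")      # multinomial by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def method_for(self, column: str) -> str:
        if column in self.methods:
            return self.methods[column]
        return "multinomial" if column in self.categorical else "pmm"


def pmm_column(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive-mean-matching draws for the missing rows of one variable."""
    y_obs = np.asarray(y_obs, dtype=float)
    n_obs = y_obs.shape[0]
    if n_obs == 0:
        raise ValueError("PMM requires at least one observed value")
    if k > n_obs:
        warnings.warn(f"PMM donor count reduced from {k} to {n_obs}")
        k = n_obs
    A_obs = np.column_stack([np.ones(n_obs), X_obs])
    beta, *_ = np.linalg.lstsq(A_obs, y_obs, rcond=None)
    pred_obs = A_obs @ beta
    A_mis = np.column_stack([np.ones(X_mis.shape[0]), X_mis])
    pred_mis = A_mis @ beta

    order = np.argsort(pred_obs, kind="stable")
    sorted_preds = pred_obs[order]
    out = np.empty(pred_mis.shape[0])
    for i, p in enumerate(pred_mis):
        j = np.searchsorted(sorted_preds, p)
        lo, hi = max(0, j - k), min(n_obs, j + k)
        window = np.arange(lo, hi)
        nearest = window[np.argsort(np.abs(sorted_preds[window] - p),
                                    kind="stable")[:k]]
        donor = nearest[rng.integers(len(nearest))]
        out[i] = y_obs[order[donor]]
    return out


def _multinomial_column(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Polytomous-regression draw for an unordered categorical variable."""
    from sklearn.linear_model import LogisticRegression

    classes = np.unique(y_obs)
    if classes.shape[0] == 1:
        return np.full(X_mis.shape[0], classes[0], dtype=float)
    model = LogisticRegression(max_iter=200)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X_obs, y_obs.astype(int))
    proba = model.predict_proba(X_mis)
    cum = np.cumsum(proba, axis=1)
    u = rng.random((X_mis.shape[0], 1))
    idx = (u > cum).sum(axis=1)
    return model.classes_[idx].astype(float)


def _imputable_columns(data: pd.DataFrame) -> list[str]:
    # time-2 outcome items are never imputed: a fabricated outcome would
    # leak into the model labels
    skip = set(ID_COLUMNS) | set(TOTAL_COLUMNS) | set(PHQ9_ITEMS_T2) | set(GAD7_ITEMS_T2)
    return [c for c in data.columns if c not in skip]


def _one_dataset(
    data: pd.DataFrame,
    spec: ImputationSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    work = data.copy()
    cols = _imputable_columns(work)
    work[cols] = work[cols].astype(float)
    missing = {c: work[c].isna().to_numpy() for c in cols}
    targets = [c for c in cols if missing[c].any()]
    # visit sequence: ascending missingness fraction
    targets.sort(key=lambda c: (missing[c].mean(), c))

    for c in targets:
        if missing[c].all():
            raise ValueError(f"column {c!r} is fully missing; cannot impute")
        obs_vals = work.loc[~missing[c], c].to_numpy(dtype=float)
        work.loc[missing[c], c] = rng.choice(obs_vals, size=missing[c].sum())

    predictors = [c for c in cols if work[c].notna().all()]
    for _ in range(spec.iterations):
        for c in targets:
            mis = missing[c]
            others = [p for p in predictors if p != c]
            X = work[others].to_numpy(dtype=float)
            y = data[c].to_numpy(dtype=float)   # original, with NaN
            if spec.method_for(c) == "multinomial":
                drawn = _multinomial_column(y[~mis], X[~mis], X[mis], rng)
            else:
                drawn = pmm_column(y[~mis], X[~mis], X[mis], spec.k, rng)
            work.loc[mis, c] = drawn
    return work


def chained_impute(
    data: pd.DataFrame, spec: ImputationSpec | None = None
) -> list[pd.DataFrame]:
    """Produce m completed datasets; observed cells are never altered."""
    spec = spec or ImputationSpec()
    cols = _imputable_columns(data)
    for c in cols:
        if data[c].isna().all():
            raise ValueError(f"column {c!r} is fully missing; cannot impute")
    if not data[cols].isna().any().any():
        return [passive_totals(data.copy()) for _ in range(spec.m)]
    root = np.random.default_rng(spec.seed)
    seeds = root.integers(0, 2**31 - 1, size=spec.m)
    return [
        passive_totals(_one_dataset(data, spec, np.random.default_rng(int(s))))
        for s in seeds
    ]


def passive_totals(data: pd.DataFrame) -> pd.DataFrame:
    """Recompute instrument totals as sums of their (possibly imputed) items."""
    out = data.copy()
    groups: list[tuple[str, Sequence[str]]] = [
        ("PHQ9_TOTAL_1", PHQ9_ITEMS),
        ("GAD7_TOTAL_1", GAD7_ITEMS),
        ("PHQ2_TOTAL_1", PHQ9_ITEMS[:2]),
        ("GAD2_TOTAL_1", GAD7_ITEMS[:2]),
        ("PHQ9_TOTAL_2", PHQ9_ITEMS_T2),
        ("GAD7_TOTAL_2", GAD7_ITEMS_T2),
    ]
    for total, items in groups:
        if all(c in out.columns for c in items):
            out[total] = out[list(items)].sum(axis=1)
    return out


def consolidate_mode(datasets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Collapse m completed datasets into one by the per-cell mode.

    Observed cells are identical across datasets, so they pass through
    unchanged; originally missing cells take the across-dataset mode, with
    ties broken toward the smallest code.  Totals are recomputed passively
    afterwards.
    """
    if len(datasets) == 0:
        raise ValueError("consolidate_mode requires at least one dataset")
    first = datasets[0]
    if len(datasets) == 1:
        return passive_totals(first.copy())
    out = first.copy()
    cols = _imputable_columns(first)
    stack = np.stack([d[cols].to_numpy(dtype=float) for d in datasets])
    m, n, p = stack.shape
    varies = (stack != stack[0]).any(axis=0)
    consolidated = stack[0].copy()
    for i, j in zip(*np.nonzero(varies)):
        values, counts = np.unique(stack[:, i, j], return_counts=True)
        consolidated[i, j] = values[counts == counts.max()].min()
    out[cols] = consolidated
    return passive_totals(out)
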