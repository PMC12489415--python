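"""Gradient-boosted future-risk models over the a-priori survey feature set.

Four model variants are trained: outcome depression (time-2 PHQ-9 >= 10) or
anxiety (time-2 GAD-7 >= 10), each with either the full symptom
questionnaires or only their first two items (PHQ-2/GAD-2) as symptom
inputs.  The eligible cohort excludes students routed to urgent assessment
or fired by the symptom rules at baseline, and requires follow-up data.
Class imbalance is addressed by grid-searching XGBoost's scale_pos_weight
over {1, negatives/positives} with stratified 10-fold cross-validation
scored by macro F1; the decision threshold is then tuned on out-of-fold
training predictions to a target sensitivity, before any test-set use.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from . import instruments as ins
from .evaluation import compute_metrics, confusion_at, tune_threshold
from .rules import RuleThresholds, evaluate_level1, evaluate_level2a

OUTCOMES = ("depression", "anxiety")
SYMPTOM_INPUTS = ("full", "abbreviated")

#: fixed boosting hyperparameters; only scale_pos_weight is grid-searched
XGB_PARAMS: dict = {
    "n_estimators": 150,
    "max_depth": 3,
    "learning_rate": 0.1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "reg_lambda": 1.0,
    "tree_method": "hist",
    "n_jobs": 1,
    "eval_metric": "logloss",
}


@dataclass(frozen=True)
class ModelVariant:
    """One of the four trained model configurations."""

    outcome: str            # "depression" | "anxiety"
    symptom_input: str      # "full" | "abbreviated"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.symptom_input not in SYMPTOM_INPUTS:
            raise ValueError(f"unknown symptom input {self.symptom_input!r}")

    @property
    def name(self) -> str:
        # conventional names: full-input models by the questionnaire that
        # defines the outcome, abbreviated by its 2-item form
        short = {"depression": "PHQ", "anxiety": "GAD"}[self.outcome]
        k = {"depression": 9, "anxiety": 7}[self.outcome]
        return f"{short}-{k}" if self.symptom_input == "full" else f"{short}-2"


ALL_VARIANTS = tuple(
    ModelVariant(o, s) for o in OUTCOMES for s in SYMPTOM_INPUTS
)


def feature_columns(variant: ModelVariant) -> list[str]:
    """Ordered feature list for a variant (fixed and recorded with the model)."""
    if variant.symptom_input == "full":
        symptom = list(ins.PHQ9_ITEMS) + list(ins.GAD7_ITEMS)
    else:
        symptom = list(ins.PHQ9_ITEMS[:2]) + list(ins.GAD7_ITEMS[:2])
    return (
        symptom
        + ["PHQ9_DIFF_1", "GAD7_DIFF_1"]
        + list(ins.BINARY_VARS)
        + list(ins.STRESS_ITEMS)
    )


@dataclass
class LabeledCohort:
    """Feature matrix, outcome labels and student ids for one variant."""

    X: pd.DataFrame
    y: np.ndarray
    ids: pd.Index

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("feature matrix and labels disagree on length")


def has_followup(data: pd.DataFrame) -> pd.Series:
    """Rows with complete time-2 instruments."""
    t2 = list(ins.PHQ9_ITEMS_T2 + ins.GAD7_ITEMS_T2)
    return data[t2].notna().all(axis=1)


def select_ml_cohort(
    decoded: pd.DataFrame,
    cfg: RuleThresholds | None = None,
    dictionary: ins.ScaleDictionary | None = None,
) -> pd.DataFrame:
    """Students eligible for risk modelling.

    Keeps rows that are not urgent under level 1, are not fired by the
    level 2a symptom rules, and have follow-up data.
    """
    cfg = cfg or RuleThresholds()
    dictionary = dictionary or ins.ScaleDictionary.default()
    keep = []
    followup = has_followup(decoded)
    for idx, row in zip(decoded.index, decoded.to_dict("records")):
        if not followup.loc[idx]:
            continue
        profile = ins.score_profile(
            row, dictionary,
            band_edges=cfg.band_edges, impairment_cut=cfg.impairment_cut,
        )
        if evaluate_level1(profile, cfg).urgent:
            continue
        if evaluate_level2a(profile, cfg) is not None:
            continue
        keep.append(idx)
    if not keep:
        raise ValueError(
            "no students eligible for risk modelling; use a larger cohort"
        )
    return decoded.loc[keep]


def build_features(decoded: pd.DataFrame, variant: ModelVariant) -> LabeledCohort:
    """Numeric design matrix and outcome labels for one variant.

    Features are baseline-only; the label is 1 iff the variant's time-2
    instrument total is at or above the clinical screening cut of 10.
    """
    cols = feature_columns(variant)
    missing = [c for c in cols if c not in decoded.columns]
    if missing:
        raise ValueError(f"missing required feature columns: {missing}")
    X = decoded[cols].astype(float).copy()
    t2 = ins.PHQ9_ITEMS_T2 if variant.outcome == "depression" else ins.GAD7_ITEMS_T2
    totals = decoded[list(t2)].sum(axis=1)
    y = (totals >= ins.SCREEN_CUT).to_numpy().astype(int)
    return LabeledCohort(X=X, y=y, ids=decoded.index)


def split_stratified(
    cohort: LabeledCohort, ratio: float = 0.7, seed: int = 0
) -> tuple[LabeledCohort, LabeledCohort]:
    """Disjoint, exhaustive train/test partition stratified by outcome."""
    counts = np.bincount(cohort.y, minlength=2)
    if counts.min() < 2:
        raise ValueError("both outcome classes need at least 2 members")
    idx_train, idx_test = train_test_split(
        np.arange(len(cohort.y)),
        train_size=ratio,
        stratify=cohort.y,
        random_state=seed,
    )
    def take(idx: np.ndarray) -> LabeledCohort:
        return LabeledCohort(
            X=cohort.X.iloc[idx], y=cohort.y[idx], ids=cohort.ids[idx]
        )
    return take(np.sort(idx_train)), take(np.sort(idx_test))


@dataclass
class RiskModel:
    """A fitted booster plus its tuned threshold and training metadata."""

    estimator: XGBClassifier
    variant: ModelVariant
    threshold: float
    scale_pos_weight: float
    cv_table: pd.DataFrame
    seed: int
    feature_names: tuple[str, ...]
    target_sensitivity: float

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.estimator.get_booster().save_model(str(directory / "model.ubj"))
        meta = {
            "outcome": self.variant.outcome,
            "symptom_input": self.variant.symptom_input,
            "threshold": self.threshold,
            "scale_pos_weight": self.scale_pos_weight,
            "seed": self.seed,
            "feature_names": list(self.feature_names),
            "target_sensitivity": self.target_sensitivity,
            "cv_table": self.cv_table.to_dict("records"),
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "RiskModel":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        est = XGBClassifier()
        est.load_model(str(directory / "model.ubj"))
        return cls(
            estimator=est,
            variant=ModelVariant(meta["outcome"], meta["symptom_input"]),
            threshold=meta["threshold"],
            scale_pos_weight=meta["scale_pos_weight"],
            cv_table=pd.DataFrame(meta["cv_table"]),
            seed=meta["seed"],
            feature_names=tuple(meta["feature_names"]),
            target_sensitivity=meta["target_sensitivity"],
        )


def _macro_f1(y_true: np.ndarray, proba: np.ndarray) -> float:
    report = compute_metrics(confusion_at(y_true, proba, 0.5))
    return report.f1_macro if report.f1_macro is not None else 0.0


def _folds(y: np.ndarray, cv_folds: int, seed: int):
    """Stratified folds; reshuffles (with warning) if a fold is degenerate."""
    for attempt in range(5):
        kf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=seed + attempt)
        folds = list(kf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            if attempt:
                warnings.warn("degenerate CV fold encountered; refolded")
            return folds
    raise ValueError("could not build non-degenerate stratified folds")


def train_model(
    train: LabeledCohort,
    variant: ModelVariant,
    grid: Sequence[float] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    target_sensitivity: float = 0.93,
    n_estimators: int | None = None,
) -> RiskModel:
    """Cross-validated scale_pos_weight selection, refit, and threshold tuning.

    The grid defaults to {1, negatives/positives}.  The winning setting (by
    mean out-of-fold macro F1; ties favour the earlier grid point) is refit
    on the full training set, and the decision threshold is tuned on the
    winning setting's out-of-fold predictions so test data never informs it.
    """
    y = train.y
    X = train.X.to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")
    if grid is None:
        grid = [1.0, n_neg / n_pos]
    params = dict(XGB_PARAMS)
    if n_estimators is not None:
        params["n_estimators"] = n_estimators

    folds = _folds(y, cv_folds, seed)
    cv_rows = []
    oof_by_spw: dict[float, np.ndarray] = {}
    for spw in grid:
        oof = np.zeros_like(y, dtype=float)
        scores = []
        for fold_id, (tr, va) in enumerate(folds):
            est = XGBClassifier(
                **params, scale_pos_weight=spw, random_state=seed)
            est.fit(X[tr], y[tr])
            proba = est.predict_proba(X[va])[:, 1]
            oof[va] = proba
            scores.append(_macro_f1(y[va], proba))
            cv_rows.append({
                "scale_pos_weight": spw, "fold": fold_id,
                "macro_f1": scores[-1],
            })
        oof_by_spw[spw] = oof
    cv_table = pd.DataFrame(cv_rows)
    means = cv_table.groupby("scale_pos_weight", sort=False)["macro_f1"].mean()
    best_spw = float(means.idxmax())

    final = XGBClassifier(**params, scale_pos_weight=best_spw, random_state=seed)
    final.fit(X, y)
    threshold = tune_threshold(y, oof_by_spw[best_spw], target_sensitivity)
    return RiskModel(
        estimator=final,
        variant=variant,
        threshold=float(threshold),
        scale_pos_weight=best_spw,
        cv_table=cv_table,
        seed=seed,
        feature_names=tuple(train.X.columns),
        target_sensitivity=target_sensitivity,
    )


def predict_risk(model: RiskModel, features: pd.DataFrame) -> np.ndarray:
    """Per-student risk probabilities; columns must match training order."""
    got = tuple(features.columns)
    if got != model.feature_names:
        raise ValueError(
            "feature columns do not match training order; expected "
            f"{list(model.feature_names)}, got {list(got)}"
        )
    return model.estimator.predict_proba(features.to_numpy(dtype=float))[:, 1]


def classify_risk(model: RiskModel, features: pd.DataFrame) -> np.ndarray:
    """Boolean risk classification at the model's tuned threshold."""
    return predict_risk(model, features) >= model.threshold
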