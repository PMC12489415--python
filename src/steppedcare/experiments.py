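"""Reproducible simulation experiments over the full modelling pipeline.

These drive the package's self-validation: the sensitivity-targeted tuning
experiment (train all four variants on a synthetic cohort, tune thresholds
on out-of-fold training predictions, evaluate held out), the null-signal
check (no planted effects: held-out AUC should sit at chance), and planted
signal recovery (AUC above chance and the strongest planted single feature
highly ranked by Shapley importance).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .evaluation import compute_metrics, confusion_at
from .explain import shap_summary
from .instruments import BINARY_VARS, decode_raw
from .models import (
    ALL_VARIANTS,
    XGB_PARAMS,
    ModelVariant,
    build_features,
    predict_risk,
    split_stratified,
    train_model,
)
from .simulate import CohortConfig, generate_cohort, label_followup


def _complete_cohort(config: CohortConfig) -> pd.DataFrame:
    """Decoded baseline + follow-up table with no injected missingness."""
    return decode_raw(label_followup(generate_cohort(config), config))


def tuned_variant_metrics(
    seed: int,
    n: int = 2285,
    prevalence: float = 0.21,
    target_sensitivity: float = 0.93,
    cv_folds: int = 10,
    ratio: float = 0.7,
    variants: Sequence[ModelVariant] = ALL_VARIANTS,
) -> pd.DataFrame:
    """Train and tune every variant on one seeded cohort; evaluate held out.

    Returns one row per variant with held-out sensitivity, specificity,
    PPV, NPV, AUC, and the tuned threshold.
    """
    config = CohortConfig(n=n, seed=seed, target_prevalence=prevalence)
    decoded = _complete_cohort(config)
    rows = []
    for variant in variants:
        cohort = build_features(decoded, variant)
        train, test = split_stratified(cohort, ratio=ratio, seed=seed)
        model = train_model(
            train, variant, cv_folds=cv_folds, seed=seed,
            target_sensitivity=target_sensitivity,
        )
        scores = predict_risk(model, test.X)
        report = compute_metrics(confusion_at(test.y, scores, model.threshold))
        rows.append({
            "seed": seed,
            "variant": variant.name,
            "outcome": variant.outcome,
            "symptom_input": variant.symptom_input,
            "threshold": model.threshold,
            "scale_pos_weight": model.scale_pos_weight,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "ppv": report.ppv,
            "npv": report.npv,
            "auc": roc_auc_score(test.y, scores),
        })
    return pd.DataFrame(rows)


def run_tuning_experiment(
    seeds: Iterable[int], **kwargs
) -> pd.DataFrame:
    """The tuning experiment across a seed set; one row per seed x variant."""
    return pd.concat(
        [tuned_variant_metrics(seed, **kwargs) for seed in seeds],
        ignore_index=True,
    )


def summarize_tuning(results: pd.DataFrame) -> pd.DataFrame:
    """Median held-out metrics per variant across seeds."""
    return (
        results.groupby("variant", sort=False)[
            ["sensitivity", "specificity", "ppv", "npv", "auc"]
        ]
        .median()
        .reset_index()
    )


def _quick_fit_auc(
    decoded: pd.DataFrame, variant: ModelVariant, seed: int, ratio: float = 0.7
) -> tuple[float, object, object]:
    """Single 70:30 fit; returns (held-out AUC, model, test cohort)."""
    from .models import LabeledCohort, RiskModel  # noqa: F401  (typing aid)

    cohort = build_features(decoded, variant)
    train, test = split_stratified(cohort, ratio=ratio, seed=seed)
    est = XGBClassifier(**XGB_PARAMS, scale_pos_weight=1.0, random_state=seed)
    est.fit(train.X.to_numpy(dtype=float), train.y)
    scores = est.predict_proba(test.X.to_numpy(dtype=float))[:, 1]
    from .models import RiskModel as _RM

    model = _RM(
        estimator=est, variant=variant, threshold=0.5, scale_pos_weight=1.0,
        cv_table=pd.DataFrame(), seed=seed,
        feature_names=tuple(train.X.columns), target_sensitivity=0.93,
    )
    return float(roc_auc_score(test.y, scores)), model, test


def null_auc(seed: int, n: int = 5000) -> float:
    """Held-out AUC when the generator plants no effects (chance level)."""
    config = CohortConfig(n=n, seed=seed, coefficients={})
    decoded = _complete_cohort(config)
    auc, _, _ = _quick_fit_auc(decoded, ModelVariant("anxiety", "full"), seed)
    return auc


def strongest_planted_feature(
    decoded: pd.DataFrame, coefficients: dict[str, float]
) -> str:
    """The planted term with the largest effect on the linear predictor.

    Strength is |coefficient| x SD of the term in the generated data.  The
    instrument-total terms compete on the total's SD — their effect is
    spread across the item features, so Shapley recovery is checked on the
    matching item-group attribution (see :func:`planted_recovery`).
    """
    from .instruments import GAD7_ITEMS, PHQ9_ITEMS

    best_name, best_strength = None, -np.inf
    for name, coef in coefficients.items():
        if name == "phq9_total":
            col = decoded[list(PHQ9_ITEMS)].sum(axis=1).to_numpy(dtype=float)
        elif name == "gad7_total":
            col = decoded[list(GAD7_ITEMS)].sum(axis=1).to_numpy(dtype=float)
        else:
            col = decoded[name].to_numpy(dtype=float)
        strength = abs(coef) * float(np.std(col))
        if strength > best_strength:
            best_name, best_strength = name, strength
    if best_name is None:
        raise ValueError("no coefficients planted")
    return best_name


def planted_recovery(
    seed: int,
    n: int = 2285,
    variant: ModelVariant = ModelVariant("anxiety", "full"),
    coefficients: dict[str, float] | None = None,
) -> dict:
    """Held-out AUC plus the Shapley rank of the strongest planted term.

    Attributions are ranked at the planted-term level: item attributions of
    each symptom instrument are pooled into its total-burden term (exact
    under Shapley additivity), single-feature terms stay as they are.
    """
    from .explain import grouped_ranking
    from .instruments import GAD7_ITEMS, PHQ9_ITEMS

    config = CohortConfig(n=n, seed=seed)
    if coefficients is not None:
        config.coefficients = dict(coefficients)
    decoded = _complete_cohort(config)
    auc, model, test = _quick_fit_auc(decoded, variant, seed)
    attributions, _ = shap_summary(model, test.X)
    groups = {}
    for name, items in (("phq9_total", PHQ9_ITEMS), ("gad7_total", GAD7_ITEMS)):
        cols = [c for c in items if c in attributions.values.columns]
        if cols:
            groups[name] = cols
    ranking = grouped_ranking(attributions, groups)
    target = strongest_planted_feature(decoded, config.coefficients)
    rank = int(ranking.loc[ranking["feature"] == target, "rank"].iloc[0])
    return {
        "auc": auc,
        "strongest_feature": target,
        "strongest_feature_rank": rank,
    }
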