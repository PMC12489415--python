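"""Shapley-value feature attributions for the fitted risk models.

Attributions are exact tree-path Shapley values computed natively by
XGBoost on the margin (log-odds) scale, where local accuracy is exact:
for every student the attributions plus the base value reproduce the
model's margin prediction.  Feature importance for reporting is the mean
absolute attribution over all evaluated predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost

from .models import RiskModel

ADDITIVITY_TOL = 1e-6


@dataclass
class AttributionMatrix:
    """Per-student, per-feature margin-scale Shapley contributions.

    Row sums plus the base value reproduce the model's margin prediction to
    within 1e-6 relative to the prediction magnitude (single-precision
    storage; see :func:`additivity_check`).
    """

    values: pd.DataFrame          # rows = students, columns = features
    base_value: float

    @property
    def mean_abs(self) -> pd.Series:
        return self.values.abs().mean(axis=0)


def shap_summary(
    model: RiskModel, features: pd.DataFrame
) -> tuple[AttributionMatrix, pd.DataFrame]:
    """Exact tree Shapley attributions plus the ranked feature table.

    The ranked table has one row per feature ordered by decreasing mean
    absolute contribution, with the mean feature value alongside so a
    beeswarm-style summary can be rebuilt from it.
    """
    got = tuple(features.columns)
    if got != model.feature_names:
        raise ValueError(
            "feature columns do not match training order; expected "
            f"{list(model.feature_names)}, got {list(got)}"
        )
    booster = model.estimator.get_booster()
    dmat = xgboost.DMatrix(features.to_numpy(dtype=float),
                           feature_names=list(features.columns))
    contribs = booster.predict(dmat, pred_contribs=True)
    values = pd.DataFrame(
        contribs[:, :-1], columns=features.columns, index=features.index
    ).astype(float)
    base_value = float(contribs[0, -1])
    attributions = AttributionMatrix(values=values, base_value=base_value)
    ranking = pd.DataFrame({
        "feature": attributions.mean_abs.sort_values(ascending=False).index,
    })
    ranking["mean_abs_shap"] = attributions.mean_abs.loc[ranking["feature"]].to_numpy()
    ranking["mean_feature_value"] = features[ranking["feature"]].mean().to_numpy()
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return attributions, ranking.reset_index(drop=True)


def grouped_ranking(
    attributions: AttributionMatrix,
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Feature ranking with some columns pooled into named groups.

    Shapley additivity makes the group attribution exact: the contribution
    of a set of features is the row-wise sum of their contributions.  Used
    to rank an instrument's total burden (items pooled) against single
    features.
    """
    pooled: dict[str, pd.Series] = {}
    used: set[str] = set()
    for name, cols in groups.items():
        pooled[name] = attributions.values[cols].sum(axis=1)
        used.update(cols)
    for col in attributions.values.columns:
        if col not in used:
            pooled[col] = attributions.values[col]
    mean_abs = pd.DataFrame(pooled).abs().mean(axis=0).sort_values(ascending=False)
    out = pd.DataFrame({"feature": mean_abs.index, "mean_abs_shap": mean_abs.to_numpy()})
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class AdditivityReport:
    passed: bool
    max_deviation: float
    worst_row: int | None


def additivity_check(
    attributions: AttributionMatrix,
    model: RiskModel,
    features: pd.DataFrame,
    tol: float = ADDITIVITY_TOL,
) -> AdditivityReport:
    """Row-wise local-accuracy check against the model's margin predictions.

    Attributions are stored in single precision, so the tolerance applies
    relative to the prediction magnitude (with a floor of one margin unit).
    """
    booster = model.estimator.get_booster()
    dmat = xgboost.DMatrix(features.to_numpy(dtype=float))
    margin = booster.predict(dmat, output_margin=True)
    recon = attributions.values.sum(axis=1).to_numpy() + attributions.base_value
    scale = np.maximum(1.0, np.abs(margin))
    dev = np.abs(recon - margin) / scale
    worst = int(np.argmax(dev)) if dev.size else None
    max_dev = float(dev.max()) if dev.size else 0.0
    return AdditivityReport(
        passed=bool(max_dev <= tol), max_deviation=max_dev, worst_row=worst
    )
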