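"""Cohort CSV reading/writing, run configuration, and the end-to-end pipeline.

CSV dialect: UTF-8, comma separated, mandatory header row, empty string for
missing; follow-up columns carry the ``_2`` suffix.  The pipeline executes
simulate -> impute -> triage -> train -> tune -> evaluate -> explain ->
engine and writes per-student recommendations, model metrics, feature
attributions and a run manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import instruments as ins
from .evaluation import compute_metrics, confusion_at
from .explain import shap_summary
from .imputation import ImputationSpec, chained_impute, consolidate_mode
from .models import (
    ModelVariant,
    build_features,
    has_followup,
    predict_risk,
    select_ml_cohort,
    split_stratified,
    train_model,
)
from .rules import RuleThresholds, run_engine
from .simulate import CohortConfig, generate_cohort, inject_missingness, label_followup

logger = logging.getLogger("steppedcare")

#: columns a cohort CSV must provide
MANDATORY_COLUMNS = (
    ("student_id", "term_index")
    + ins.PHQ9_ITEMS + ("PHQ9_DIFF_1",)
    + ins.GAD7_ITEMS + ("GAD7_DIFF_1",)
    + ins.STRESS_ITEMS + ins.BINARY_VARS + ins.SUBSTANCE_VARS
)


def read_cohort(
    path: str | Path,
    dictionary: ins.ScaleDictionary | None = None,
    decode: bool = True,
) -> pd.DataFrame:
    """Read and (optionally) decode a cohort CSV, validating its schema."""
    data = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    if decode:
        data = ins.decode_raw(data, dictionary)
    return data


def write_cohort(data: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data.to_csv(path, index=False)
    return path


class SimulateSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 2285
    target_prevalence: float = 0.21
    missing_rate: float = 0.05
    missing_mechanism: Literal["MCAR", "MAR"] = "MCAR"
    followup_rate: float = 1.0


class ImputeSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    m: int = 10
    iterations: int = 10
    k: int = 5


class RulesSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    evaluate_l2bc_on_all: bool = False
    include_ideation_in_level1: bool = False


class ModelSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variants: list[str] = Field(
        default_factory=lambda: [
            "depression:full", "anxiety:full",
            "depression:abbreviated", "anxiety:abbreviated",
        ]
    )
    target_sensitivity: float = 0.93
    cv_folds: int = 10
    train_ratio: float = 0.7
    n_estimators: int | None = None

    def parsed_variants(self) -> list[ModelVariant]:
        out = []
        for spec in self.variants:
            outcome, _, symptom = spec.partition(":")
            out.append(ModelVariant(outcome, symptom or "full"))
        return out


class EngineConfig(BaseModel):
    """Validated top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    input_csv: str | None = None     # when None, a cohort is simulated
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    imputation: ImputeSettings = Field(default_factory=ImputeSettings)
    rules: RulesSettings = Field(default_factory=RulesSettings)
    models: ModelSettings = Field(default_factory=ModelSettings)
    out_dir: str = "steppedcare_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "EngineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _rule_thresholds(config: EngineConfig) -> RuleThresholds:
    return RuleThresholds(
        evaluate_l2bc_on_all=config.rules.evaluate_l2bc_on_all,
        include_ideation_in_level1=config.rules.include_ideation_in_level1,
    )


def _cohort_config(config: EngineConfig) -> CohortConfig:
    s = config.simulate
    return CohortConfig(
        n=s.n, seed=config.seed, target_prevalence=s.target_prevalence,
        missing_rate=s.missing_rate, missing_mechanism=s.missing_mechanism,
        followup_rate=s.followup_rate,
    )


def recommend_pipeline(config: EngineConfig) -> Path:
    """Run the whole engine end to end; returns the run directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dictionary = ins.ScaleDictionary.default()
    cfg = _rule_thresholds(config)
    counts: dict[str, int] = {}

    # --- acquire cohort -------------------------------------------------
    if config.input_csv is not None:
        raw = read_cohort(config.input_csv, dictionary, decode=False)
    else:
        cc = _cohort_config(config)
        raw = label_followup(generate_cohort(cc), cc)
        if cc.missing_rate > 0:
            raw, _ = inject_missingness(raw, cc)
    counts["cohort"] = len(raw)
    logger.info("stage=cohort n=%d", len(raw))

    decoded = ins.decode_raw(raw, dictionary)

    # --- impute ----------------------------------------------------------
    spec = ImputationSpec(
        m=config.imputation.m, iterations=config.imputation.iterations,
        k=config.imputation.k, seed=config.seed,
    )
    completed = chained_impute(decoded, spec)
    data = consolidate_mode(completed)
    logger.info("stage=impute m=%d", spec.m)

    # --- triage (rules only, ML joined below) ----------------------------
    profiles = ins.score_cohort(
        data, dictionary,
        band_edges=cfg.band_edges, impairment_cut=cfg.impairment_cut,
    )

    # --- ML cohort, training, evaluation ---------------------------------
    ml = select_ml_cohort(data, cfg, dictionary)
    counts["ml_eligible"] = len(ml)
    logger.info("stage=ml_cohort n=%d", len(ml))
    metrics: dict[str, dict] = {}
    trained = {}
    for variant in config.models.parsed_variants():
        cohort = build_features(ml, variant)
        train, test = split_stratified(
            cohort, ratio=config.models.train_ratio, seed=config.seed)
        model = train_model(
            train, variant,
            cv_folds=config.models.cv_folds, seed=config.seed,
            target_sensitivity=config.models.target_sensitivity,
            n_estimators=config.models.n_estimators,
        )
        scores = predict_risk(model, test.X)
        report = compute_metrics(confusion_at(test.y, scores, model.threshold))
        metrics[variant.name] = {
            "threshold": model.threshold,
            "scale_pos_weight": model.scale_pos_weight,
            **{k: v for k, v in report.to_dict().items()},
        }
        _, ranking = shap_summary(model, test.X)
        ranking.to_csv(out_dir / f"ranked_features_{variant.name}.csv", index=False)
        model.save(out_dir / f"model_{variant.name}")
        trained[(variant.outcome, variant.symptom_input)] = model
        logger.info("stage=train variant=%s threshold=%.3f",
                    variant.name, model.threshold)
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))

    # --- integrated engine ------------------------------------------------
    full_models = [
        m for (outcome, symptom), m in trained.items() if symptom == "full"
    ] or list(trained.values())
    if full_models:
        ml_flags = np.zeros(len(data), dtype=bool)
        for model in full_models:
            X = data[list(model.feature_names)].astype(float)
            ml_flags |= predict_risk(model, X) >= model.threshold
    else:
        ml_flags = np.full(len(data), None)
    rows = []
    for profile, ml_positive in zip(profiles, ml_flags):
        result = run_engine(profile, cfg, ml_positive=ml_positive)
        rows.append({
            "student_id": profile.student_id,
            "stage": result.stage_reached.value,
            "urgent": result.urgent,
            "low": result.final.low.name,
            "high": result.final.high.name,
            "rationale": ";".join(result.final.rationale),
        })
    recs = pd.DataFrame(rows)
    recs.to_csv(out_dir / "recommendations.csv", index=False)
    counts["urgent"] = int(recs["urgent"].sum())
    counts["no_recommendation"] = int((recs["high"] == "NONE").sum())
    logger.info("stage=engine urgent=%d none=%d",
                counts["urgent"], counts["no_recommendation"])

    # --- manifest ----------------------------------------------------------
    config_json = config.model_dump()
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_json,
        "config_sha256": hashlib.sha256(
            json.dumps(config_json, sort_keys=True).encode()
        ).hexdigest(),
        "stage_counts": counts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
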