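"""Stepped-care triage rules and the engine that integrates them with ML risk.

Level 1 screens for urgency: lifetime suicide attempt or self-harm together
with current suicidal thoughts (PHQ-9 item 9) routes to urgent in-person
assessment; if exactly one of the two is positive, urgency additionally
requires severe debilitating depression or current substance use.

Non-urgent students flow to level 2a (symptom severity x impairment/stress),
and — only if 2a does not fire — in parallel to level 2b (lifetime
diagnosis history), level 2c (substance use) and the ML future-risk models.
The final signposting is the highest care level any rule recommends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Mapping, Sequence

from .instruments import (
    DEFAULT_BAND_EDGES,
    IMPAIRMENT_CUT,
    ScoredProfile,
    Severity,
)


class CareLevel(IntEnum):
    """Stepped care levels, ordered from least to most intensive."""

    NONE = 0
    SELF_GUIDED = 1
    COUNSELING = 2
    PRIMARY_CARE = 3
    MH_TEAM = 4
    ADDICTION_SERVICES = 5
    CRISIS_SWS = 6
    URGENT_IN_PERSON = 7


class SourceRule(str, Enum):
    LEVEL1 = "LEVEL1"
    L2A = "L2A"
    L2B = "L2B"
    L2C = "L2C"
    ML = "ML"
    NONE = "NONE"


#: tie-break priority (higher wins) when recommendations tie on both levels
_SOURCE_PRIORITY = {
    SourceRule.L2A: 4,
    SourceRule.L2B: 3,
    SourceRule.L2C: 2,
    SourceRule.ML: 1,
    SourceRule.LEVEL1: 5,
    SourceRule.NONE: 0,
}


@dataclass(frozen=True)
class Recommendation:
    """An ordered care-level range with the rule and clauses that produced it."""

    low: CareLevel
    high: CareLevel
    source_rule: SourceRule
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("recommendation low level exceeds high level")
        if self.high > CareLevel.NONE and not self.rationale:
            raise ValueError("non-trivial recommendation requires a rationale")


NO_RECOMMENDATION = Recommendation(
    CareLevel.NONE, CareLevel.NONE, SourceRule.NONE, ()
)


@dataclass(frozen=True)
class TriageOutcome:
    urgent: bool
    recommendation: Recommendation


MappingTable = Mapping[tuple[Severity, bool], tuple[CareLevel, CareLevel]]

_L = CareLevel
DEFAULT_TABLE_2A: dict[tuple[Severity, bool], tuple[CareLevel, CareLevel]] = {
    (Severity.MODERATE, False): (_L.SELF_GUIDED, _L.COUNSELING),
    (Severity.MODERATE, True): (_L.COUNSELING, _L.PRIMARY_CARE),
    (Severity.SEVERE, False): (_L.COUNSELING, _L.PRIMARY_CARE),
    (Severity.SEVERE, True): (_L.PRIMARY_CARE, _L.MH_TEAM),
    (Severity.VERY_SEVERE, False): (_L.MH_TEAM, _L.MH_TEAM),
    (Severity.VERY_SEVERE, True): (_L.MH_TEAM, _L.CRISIS_SWS),
}
DEFAULT_TABLE_2B: dict[tuple[Severity, bool], tuple[CareLevel, CareLevel]] = {
    (Severity.NONE, False): (_L.SELF_GUIDED, _L.SELF_GUIDED),
    (Severity.NONE, True): (_L.SELF_GUIDED, _L.SELF_GUIDED),
    (Severity.MODERATE, False): (_L.COUNSELING, _L.COUNSELING),
    (Severity.MODERATE, True): (_L.COUNSELING, _L.PRIMARY_CARE),
    (Severity.SEVERE, False): (_L.PRIMARY_CARE, _L.MH_TEAM),
    (Severity.SEVERE, True): (_L.MH_TEAM, _L.MH_TEAM),
    (Severity.VERY_SEVERE, False): (_L.MH_TEAM, _L.MH_TEAM),
    (Severity.VERY_SEVERE, True): (_L.MH_TEAM, _L.CRISIS_SWS),
}
DEFAULT_TABLE_2C: dict[tuple[Severity, bool], tuple[CareLevel, CareLevel]] = {
    (Severity.NONE, False): (_L.SELF_GUIDED, _L.SELF_GUIDED),
    (Severity.NONE, True): (_L.SELF_GUIDED, _L.SELF_GUIDED),
    (Severity.MODERATE, False): (_L.COUNSELING, _L.COUNSELING),
    (Severity.MODERATE, True): (_L.COUNSELING, _L.PRIMARY_CARE),
    (Severity.SEVERE, False): (_L.PRIMARY_CARE, _L.MH_TEAM),
    (Severity.SEVERE, True): (_L.MH_TEAM, _L.MH_TEAM),
    (Severity.VERY_SEVERE, False): (_L.MH_TEAM, _L.ADDICTION_SERVICES),
    (Severity.VERY_SEVERE, True): (_L.ADDICTION_SERVICES, _L.CRISIS_SWS),
}


@dataclass
class RuleThresholds:
    """All tunable constants of the rules engine.

    ``severe_depression_cut`` with impairment defines "severe debilitating
    depression" in the level 1 workflow.  Mapping tables send a
    (severity band, impairment-or-stress flag) pair to a care-level range.
    """

    band_edges: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_BAND_EDGES.items()
    })
    impairment_cut: int = IMPAIRMENT_CUT
    severe_depression_cut: int = 20
    table_2a: dict = field(default_factory=lambda: dict(DEFAULT_TABLE_2A))
    table_2b: dict = field(default_factory=lambda: dict(DEFAULT_TABLE_2B))
    table_2c: dict = field(default_factory=lambda: dict(DEFAULT_TABLE_2C))
    include_ideation_in_level1: bool = False
    evaluate_l2bc_on_all: bool = False

    @staticmethod
    def _table_to_json(table: MappingTable) -> dict:
        return {
            f"{band.name}|{flag}": [lo.name, hi.name]
            for (band, flag), (lo, hi) in table.items()
        }

    @staticmethod
    def _table_from_json(obj: Mapping[str, Sequence[str]]) -> dict:
        out = {}
        for key, (lo, hi) in obj.items():
            band_name, flag = key.split("|")
            out[(Severity[band_name], flag == "True")] = (
                CareLevel[lo], CareLevel[hi],
            )
        return out

    def to_json(self) -> dict:
        return {
            "band_edges": self.band_edges,
            "impairment_cut": self.impairment_cut,
            "severe_depression_cut": self.severe_depression_cut,
            "table_2a": self._table_to_json(self.table_2a),
            "table_2b": self._table_to_json(self.table_2b),
            "table_2c": self._table_to_json(self.table_2c),
            "include_ideation_in_level1": self.include_ideation_in_level1,
            "evaluate_l2bc_on_all": self.evaluate_l2bc_on_all,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "RuleThresholds":
        kwargs = dict(obj)
        for name in ("table_2a", "table_2b", "table_2c"):
            if name in kwargs:
                kwargs[name] = cls._table_from_json(kwargs[name])
        return cls(**kwargs)


def evaluate_level1(profile: ScoredProfile, cfg: RuleThresholds | None = None) -> TriageOutcome:
    """Urgency workflow: lifetime suicidality x current suicidal thoughts."""
    cfg = cfg or RuleThresholds()
    lifetime = profile.history.attempt_or_self_harm
    if cfg.include_ideation_in_level1:
        lifetime = lifetime or profile.history.wish_dead or profile.history.ideation
    current = profile.item9_positive
    severe_debilitating = (
        profile.phq9_total >= cfg.severe_depression_cut and profile.impairment
    )
    rationale: list[str] = []
    if lifetime:
        rationale.append("lifetime_attempt_or_self_harm")
    if current:
        rationale.append("current_suicidal_thoughts")
    urgent = False
    if lifetime and current:
        urgent = True
    elif lifetime or current:
        if severe_debilitating:
            urgent = True
            rationale.append("severe_debilitating_depression")
        if profile.substances.any:
            urgent = True
            rationale.append("substance_use")
    if urgent:
        rec = Recommendation(
            CareLevel.URGENT_IN_PERSON, CareLevel.URGENT_IN_PERSON,
            SourceRule.LEVEL1, tuple(rationale),
        )
    else:
        rec = NO_RECOMMENDATION
    return TriageOutcome(urgent=urgent, recommendation=rec)


def _flag(profile: ScoredProfile) -> bool:
    return profile.impairment or profile.stress


def evaluate_level2a(
    profile: ScoredProfile, cfg: RuleThresholds | None = None
) -> Recommendation | None:
    """Symptom rules: severity band x impairment-or-stress."""
    cfg = cfg or RuleThresholds()
    if profile.band == Severity.NONE:
        return None
    low, high = cfg.table_2a[(profile.band, _flag(profile))]
    rationale = [f"band_{profile.band.name}"]
    if _flag(profile):
        rationale.append("impairment_or_stress")
    return Recommendation(low, high, SourceRule.L2A, tuple(rationale))


def evaluate_level2b(
    profile: ScoredProfile, cfg: RuleThresholds | None = None
) -> Recommendation | None:
    """Lifetime-history rules; history alone maps to self-guided support."""
    cfg = cfg or RuleThresholds()
    if not profile.history.lifetime_history:
        return None
    low, high = cfg.table_2b[(profile.band, _flag(profile))]
    rationale = ["lifetime_history", f"band_{profile.band.name}"]
    if profile.band != Severity.NONE and _flag(profile):
        rationale.append("impairment_or_stress")
    return Recommendation(low, high, SourceRule.L2B, tuple(rationale))


def evaluate_level2c(
    profile: ScoredProfile, cfg: RuleThresholds | None = None
) -> Recommendation | None:
    """Substance-use rules; use alone maps to self-guided support."""
    cfg = cfg or RuleThresholds()
    if not profile.substances.any:
        return None
    low, high = cfg.table_2c[(profile.band, _flag(profile))]
    rationale = ["substance_use", f"band_{profile.band.name}"]
    if profile.substances.binge:
        rationale.append("binge_drinking")
    if profile.substances.cannabis:
        rationale.append("cannabis_use")
    if profile.substances.any_other_drug:
        rationale.append("other_drug_use")
    if profile.band != Severity.NONE and _flag(profile):
        rationale.append("impairment_or_stress")
    return Recommendation(low, high, SourceRule.L2C, tuple(rationale))


def combine_recommendations(recs: Sequence[Recommendation]) -> Recommendation:
    """Keep the recommendation with the highest care level.

    Ties on the high level break by the higher low level, then by source
    priority (2a > 2b > 2c > ML).  The rationale is the union, in input
    order, of all contributing rationales.
    """
    if not recs:
        raise ValueError("combine_recommendations requires at least one input")
    best = max(
        recs,
        key=lambda r: (r.high, r.low, _SOURCE_PRIORITY[r.source_rule]),
    )
    seen: dict[str, None] = {}
    for r in recs:
        for clause in r.rationale:
            seen.setdefault(clause)
    return replace(best, rationale=tuple(seen))


@dataclass(frozen=True)
class EngineOutput:
    stage_reached: SourceRule
    final: Recommendation
    urgent: bool
    fired: tuple[SourceRule, ...]


def run_engine(
    profile: ScoredProfile,
    cfg: RuleThresholds | None = None,
    ml_positive: bool | None = None,
) -> EngineOutput:
    """Route one student through the integrated engine.

    ``ml_positive`` is the (already computed) future-risk classification for
    this student, or None when no models are supplied.  A positive risk
    prediction contributes a self-guided recommendation.
    """
    cfg = cfg or RuleThresholds()
    l1 = evaluate_level1(profile, cfg)
    if l1.urgent:
        return EngineOutput(SourceRule.LEVEL1, l1.recommendation, True,
                            (SourceRule.LEVEL1,))
    rec2a = evaluate_level2a(profile, cfg)
    if rec2a is not None and not cfg.evaluate_l2bc_on_all:
        return EngineOutput(SourceRule.L2A, rec2a, False, (SourceRule.L2A,))
    parallel: list[Recommendation] = []
    if rec2a is not None:
        parallel.append(rec2a)
    for evaluate in (evaluate_level2b, evaluate_level2c):
        rec = evaluate(profile, cfg)
        if rec is not None:
            parallel.append(rec)
    if ml_positive:
        parallel.append(Recommendation(
            CareLevel.SELF_GUIDED, CareLevel.SELF_GUIDED,
            SourceRule.ML, ("ml_future_risk",),
        ))
    if not parallel:
        return EngineOutput(SourceRule.NONE, NO_RECOMMENDATION, False, ())
    final = combine_recommendations(parallel)
    stage = SourceRule.L2A if (rec2a is not None and cfg.evaluate_l2bc_on_all) \
        else final.source_rule
    return EngineOutput(stage, final, False, tuple(r.source_rule for r in parallel))
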