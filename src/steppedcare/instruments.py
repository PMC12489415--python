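"""Survey decoding, instrument scoring, severity bands, and clinical flags.

The baseline survey carries the PHQ-9 and GAD-7 symptom questionnaires
(items 0-3), their follow-on functional-impairment items (DIFF, 0-3), the
PSS-4 perceived-stress scale (items 0-4, items 2 and 3 positively worded),
lifetime / family-history / childhood-adversity / suicidality yes-no items
(coded 1 = Yes, 2 = No), and past-month substance-use frequency items on
per-variable scales.  999 means "prefer not to answer" and decodes to
missing.  The cannabis item changes response scale after the first two
survey terms, which also moves its screening threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_CODE = 999

PHQ9_ITEMS = tuple(f"PHQ9_{i}_1" for i in range(1, 10))
GAD7_ITEMS = tuple(f"GAD7_{i}_1" for i in range(1, 8))
STRESS_ITEMS = tuple(f"STRESS_{i}_1" for i in range(1, 5))
DIFF_ITEMS = ("PHQ9_DIFF_1", "GAD7_DIFF_1")

LIFETIME_DIAGNOSES = ("ANXIETY_1", "MOOD_1", "PSYCHOTIC_1", "EATING_1", "NEURO_1")
OTHER_HISTORY = ("SUBSTANCE_1", "EMERGE_1")
FAMILY_HISTORY = ("FANXIETY_1", "FMOOD_1", "FPSYCHOTIC_1", "FSUBSTANCE_1")
ADVERSITY = ("REJECTED_1", "PHYSABUSE_1", "BULLYING_1", "SABUSE_1", "PDEATH_1")
SUICIDALITY = ("WISHDEAD_1", "SUICIDEA_1", "SUICATMP_1", "SELFHARM_1")
BINARY_VARS = (
    LIFETIME_DIAGNOSES + OTHER_HISTORY + FAMILY_HISTORY + ADVERSITY + SUICIDALITY
)

# Past-month substance-use items.  Weekly-scale items (0-4) screen at >=2,
# monthly-scale items (0-5) at >=3; binge drinking (0-4) screens at weekly
# use, >=3.  Cannabis switches dialect with the survey term.
SUBSTANCE_VARS = (
    "SLEEPING_1", "STIM_1", "CANNABIS_1", "OPIATE_1", "PSYCHEDELIC_1",
    "COCAINE_1", "STREET_1", "RXMISUSE_1", "ACADEMIC_1", "BINGE_1",
)

PHQ9_ITEMS_T2 = tuple(f"PHQ9_{i}_2" for i in range(1, 10))
GAD7_ITEMS_T2 = tuple(f"GAD7_{i}_2" for i in range(1, 8))

#: Default severity band edges (lower bound of each band, inclusive).
DEFAULT_BAND_EDGES: dict[str, dict[str, int]] = {
    "PHQ9": {"moderate": 10, "severe": 15, "very_severe": 20},
    "GAD7": {"moderate": 10, "severe": 15, "very_severe": 19},
}

SCREEN_CUT = 10          # PHQ-9 / GAD-7 positive screen
ABBREVIATED_CUT = 3      # PHQ-2 / GAD-2 positive screen (reporting only)
IMPAIRMENT_CUT = 2       # DIFF >= 2 ("Very difficult")


class Severity(IntEnum):
    """Combined depression/anxiety symptom band, ordered by severity."""

    NONE = 0
    MODERATE = 1
    SEVERE = 2
    VERY_SEVERE = 3


class ScaleError(ValueError):
    """A response code fell outside its declared scale."""


@dataclass(frozen=True)
class VariableScale:
    """Scale descriptor for one survey variable."""

    kind: str                      # "ordinal" | "binary" | "substance"
    low: int = 0
    high: int = 0
    threshold: int | None = None   # substance screening threshold
    dialects: Mapping[str, Mapping[str, int]] | None = None  # cannabis only

    def bounds(self, term_index: int = 1) -> tuple[int, int]:
        if self.dialects is not None:
            d = self.dialects["early"] if term_index <= 2 else self.dialects["late"]
            return d["low"], d["high"]
        if self.kind == "binary":
            return 1, 2
        return self.low, self.high

    def screen_threshold(self, term_index: int = 1) -> int | None:
        if self.dialects is not None:
            d = self.dialects["early"] if term_index <= 2 else self.dialects["late"]
            return d["threshold"]
        return self.threshold


@dataclass
class ScaleDictionary:
    """Machine-readable data dictionary mirroring the survey codebook."""

    variables: dict[str, VariableScale]
    missing_code: int = MISSING_CODE

    @classmethod
    def default(cls) -> "ScaleDictionary":
        text = resources.files("steppedcare.data").joinpath(
            "survey_dictionary.json"
        ).read_text()
        return cls.from_json(json.loads(text))

    @classmethod
    def from_json(cls, obj: dict) -> "ScaleDictionary":
        variables = {}
        for name, v in obj["variables"].items():
            variables[name] = VariableScale(
                kind=v["kind"],
                low=v.get("low", 0),
                high=v.get("high", 0),
                threshold=v.get("threshold"),
                dialects=v.get("dialects"),
            )
        return cls(variables=variables, missing_code=obj.get("missing_code", MISSING_CODE))

    def to_json(self) -> dict:
        out: dict = {"missing_code": self.missing_code, "variables": {}}
        for name, v in self.variables.items():
            entry: dict = {"kind": v.kind}
            if v.dialects is not None:
                entry["dialects"] = {k: dict(d) for k, d in v.dialects.items()}
            else:
                if v.kind != "binary":
                    entry["low"], entry["high"] = v.low, v.high
                if v.threshold is not None:
                    entry["threshold"] = v.threshold
            out["variables"][name] = entry
        return out


def decode_raw(
    data: pd.DataFrame,
    dictionary: ScaleDictionary | None = None,
) -> pd.DataFrame:
    """Decode raw survey codes into analysis values.

    999 becomes NaN, yes/no items recode 1/2 -> 1/0, and ordinal items pass
    through unchanged.  Any code outside its declared scale raises
    :class:`ScaleError` naming the variable and row.  Idempotent: decoding
    an already-decoded table is a no-op (decoded values are always within
    scale for ordinal items, and 0/1 is accepted for binary items).
    """
    dictionary = dictionary or ScaleDictionary.default()
    out = data.copy()
    term = out["term_index"] if "term_index" in out else pd.Series(1, index=out.index)
    problems: list[str] = []
    for name, scale in dictionary.variables.items():
        if name not in out.columns:
            continue
        col = pd.to_numeric(out[name], errors="coerce").astype(float)
        col = col.mask(col == dictionary.missing_code)
        if scale.kind == "binary":
            # raw coding 1=Yes 2=No; decoded coding 1/0 is also accepted
            bad = col.notna() & ~col.isin([0.0, 1.0, 2.0])
            col = col.where(col != 2.0, 0.0)
        elif scale.dialects is not None:
            lo_e, hi_e = scale.dialects["early"]["low"], scale.dialects["early"]["high"]
            lo_l, hi_l = scale.dialects["late"]["low"], scale.dialects["late"]["high"]
            lo = np.where(term <= 2, lo_e, lo_l)
            hi = np.where(term <= 2, hi_e, hi_l)
            bad = col.notna() & ((col < lo) | (col > hi))
        else:
            bad = col.notna() & ((col < scale.low) | (col > scale.high))
        if bad.any():
            rows = list(out.index[bad][:5])
            problems.append(f"{name}: out-of-scale code at rows {rows}")
        out[name] = col
    if problems:
        raise ScaleError("; ".join(problems))
    return out


def score_instrument(items: Sequence[float], instrument: str) -> int:
    """Sum a complete, decoded instrument (PHQ9/GAD7/PHQ2/GAD2)."""
    lengths = {"PHQ9": 9, "GAD7": 7, "PHQ2": 2, "GAD2": 2}
    instrument = instrument.upper()
    if instrument not in lengths:
        raise ValueError(f"unknown instrument {instrument!r}")
    arr = np.asarray(items, dtype=float)
    if arr.shape[0] != lengths[instrument]:
        raise ValueError(
            f"{instrument} expects {lengths[instrument]} items, got {arr.shape[0]}"
        )
    if np.isnan(arr).any():
        raise ValueError(f"{instrument} has missing items; impute before scoring")
    return int(arr.sum())


def screen_positive(total: int, instrument: str, cut: int | None = None) -> bool:
    """Positive screen: total >= 10 (full forms) or >= 3 (abbreviated)."""
    if cut is None:
        cut = ABBREVIATED_CUT if instrument.upper() in ("PHQ2", "GAD2") else SCREEN_CUT
    return total >= cut


def _band_one(total: int, edges: Mapping[str, int]) -> Severity:
    if total >= edges["very_severe"]:
        return Severity.VERY_SEVERE
    if total >= edges["severe"]:
        return Severity.SEVERE
    if total >= edges["moderate"]:
        return Severity.MODERATE
    return Severity.NONE


def severity_band(
    phq9_total: int,
    gad7_total: int,
    edges: Mapping[str, Mapping[str, int]] | None = None,
) -> Severity:
    """Combined band = the more severe of the per-instrument bands."""
    edges = edges or DEFAULT_BAND_EDGES
    return max(_band_one(phq9_total, edges["PHQ9"]), _band_one(gad7_total, edges["GAD7"]))


def stress_flag(pss4_items: Sequence[float]) -> bool:
    """Overwhelming-stress clause over the four PSS-4 items.

    Items 1 and 4 are negatively worded (high = stressed), items 2 and 3
    positively worded (low = stressed): flag iff Q1 >= 3 or Q4 >= 3 or
    Q2 <= 1 or Q3 <= 1.
    """
    q = np.asarray(pss4_items, dtype=float)
    if q.shape[0] != 4:
        raise ValueError("PSS-4 expects 4 items")
    if np.isnan(q).any():
        raise ValueError("PSS-4 has missing items; impute before flagging")
    return bool(q[0] >= 3 or q[3] >= 3 or q[1] <= 1 or q[2] <= 1)


def impairment_flag(
    phq_diff: float, gad_diff: float, cut: int = IMPAIRMENT_CUT
) -> bool:
    """Functional impairment: either DIFF item at or above the cut.

    Structurally absent DIFF responses count as not impaired.
    """
    vals = [0.0 if (v is None or (isinstance(v, float) and np.isnan(v))) else float(v)
            for v in (phq_diff, gad_diff)]
    return max(vals) >= cut


@dataclass(frozen=True)
class SubstanceFlags:
    binge: bool
    cannabis: bool
    any_other_drug: bool

    @property
    def any(self) -> bool:
        return self.binge or self.cannabis or self.any_other_drug


def substance_flags(
    row: Mapping[str, float],
    term_index: int = 1,
    dictionary: ScaleDictionary | None = None,
) -> SubstanceFlags:
    """Per-variable scale-aware substance screening; missing counts as no use."""
    dictionary = dictionary or ScaleDictionary.default()

    def hit(name: str) -> bool:
        val = row.get(name)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return False
        thr = dictionary.variables[name].screen_threshold(term_index)
        return float(val) >= thr

    other = [v for v in SUBSTANCE_VARS if v not in ("BINGE_1", "CANNABIS_1")]
    return SubstanceFlags(
        binge=hit("BINGE_1"),
        cannabis=hit("CANNABIS_1"),
        any_other_drug=any(hit(v) for v in other),
    )


@dataclass(frozen=True)
class HistoryFlags:
    lifetime_history: bool             # any lifetime mental-disorder diagnosis
    family: dict[str, bool]
    adversity: dict[str, bool]
    wish_dead: bool
    ideation: bool
    attempt: bool
    self_harm: bool

    @property
    def attempt_or_self_harm(self) -> bool:
        return self.attempt or self.self_harm


def _as_bool(val: object) -> bool:
    if val is None:
        return False
    v = float(val)
    if np.isnan(v):
        return False
    return v >= 0.5


def history_flags(row: Mapping[str, float]) -> HistoryFlags:
    """Lifetime-diagnosis, family-history, adversity and suicidality flags."""
    return HistoryFlags(
        lifetime_history=any(_as_bool(row.get(v)) for v in LIFETIME_DIAGNOSES),
        family={v: _as_bool(row.get(v)) for v in FAMILY_HISTORY},
        adversity={v: _as_bool(row.get(v)) for v in ADVERSITY},
        wish_dead=_as_bool(row.get("WISHDEAD_1")),
        ideation=_as_bool(row.get("SUICIDEA_1")),
        attempt=_as_bool(row.get("SUICATMP_1")),
        self_harm=_as_bool(row.get("SELFHARM_1")),
    )


@dataclass(frozen=True)
class ScoredProfile:
    """Derived totals, severity band and clinical flags for one student."""

    student_id: str
    phq9_total: int
    gad7_total: int
    phq2_total: int
    gad2_total: int
    band: Severity
    impairment: bool
    stress: bool
    history: HistoryFlags
    substances: SubstanceFlags
    phq9_item9: int          # current suicidal-thought item
    term_index: int = 1

    @property
    def item9_positive(self) -> bool:
        return self.phq9_item9 >= 1


def score_profile(
    row: Mapping[str, float],
    dictionary: ScaleDictionary | None = None,
    band_edges: Mapping[str, Mapping[str, int]] | None = None,
    impairment_cut: int = IMPAIRMENT_CUT,
) -> ScoredProfile:
    """Score one decoded (and, for symptom items, complete) survey row."""
    dictionary = dictionary or ScaleDictionary.default()
    phq = [row[v] for v in PHQ9_ITEMS]
    gad = [row[v] for v in GAD7_ITEMS]
    phq9_total = score_instrument(phq, "PHQ9")
    gad7_total = score_instrument(gad, "GAD7")
    term = int(row.get("term_index", 1))
    return ScoredProfile(
        student_id=str(row.get("student_id", "")),
        phq9_total=phq9_total,
        gad7_total=gad7_total,
        phq2_total=score_instrument(phq[:2], "PHQ2"),
        gad2_total=score_instrument(gad[:2], "GAD2"),
        band=severity_band(phq9_total, gad7_total, band_edges),
        impairment=impairment_flag(
            row.get("PHQ9_DIFF_1", np.nan), row.get("GAD7_DIFF_1", np.nan),
            cut=impairment_cut,
        ),
        stress=stress_flag([row[v] for v in STRESS_ITEMS]),
        history=history_flags(row),
        substances=substance_flags(row, term, dictionary),
        phq9_item9=int(row["PHQ9_9_1"]),
        term_index=term,
    )


def score_cohort(
    data: pd.DataFrame,
    dictionary: ScaleDictionary | None = None,
    **kwargs,
) -> list[ScoredProfile]:
    """Score every row of a decoded cohort table."""
    dictionary = dictionary or ScaleDictionary.default()
    return [
        score_profile(row, dictionary, **kwargs)
        for row in data.to_dict("records")
    ]


def build_default_dictionary() -> ScaleDictionary:
    """Construct the shipped codebook programmatically (single source of truth)."""
    variables: dict[str, VariableScale] = {}
    for v in PHQ9_ITEMS + GAD7_ITEMS + PHQ9_ITEMS_T2 + GAD7_ITEMS_T2 + DIFF_ITEMS:
        variables[v] = VariableScale(kind="ordinal", low=0, high=3)
    for v in STRESS_ITEMS:
        variables[v] = VariableScale(kind="ordinal", low=0, high=4)
    for v in BINARY_VARS:
        variables[v] = VariableScale(kind="binary")
    weekly = ("SLEEPING_1", "STIM_1", "OPIATE_1", "PSYCHEDELIC_1")
    monthly = ("COCAINE_1", "STREET_1", "RXMISUSE_1", "ACADEMIC_1")
    for v in weekly:
        variables[v] = VariableScale(kind="substance", low=0, high=4, threshold=2)
    for v in monthly:
        variables[v] = VariableScale(kind="substance", low=0, high=5, threshold=3)
    variables["BINGE_1"] = VariableScale(kind="substance", low=0, high=4, threshold=3)
    variables["CANNABIS_1"] = VariableScale(
        kind="substance",
        dialects={
            "early": {"low": 0, "high": 4, "threshold": 2},
            "late": {"low": 0, "high": 5, "threshold": 3},
        },
    )
    return ScaleDictionary(variables=variables)
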