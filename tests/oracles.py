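"""Independent brute-force oracles used by unit and acceptance tests.

These re-derive expected results from first principles (literal formulas,
literal rule tables, plain tabulation) without calling the implementation
code paths they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from steppedcare.instruments import Severity
from steppedcare.rules import CareLevel

L = CareLevel

# Literal care-range tables as printed-count decompositions imply them:
# (band, impairment-or-stress) -> (low, high).
ORACLE_2A = {
    (Severity.MODERATE, False): (L.SELF_GUIDED, L.COUNSELING),
    (Severity.MODERATE, True): (L.COUNSELING, L.PRIMARY_CARE),
    (Severity.SEVERE, False): (L.COUNSELING, L.PRIMARY_CARE),
    (Severity.SEVERE, True): (L.PRIMARY_CARE, L.MH_TEAM),
    (Severity.VERY_SEVERE, False): (L.MH_TEAM, L.MH_TEAM),
    (Severity.VERY_SEVERE, True): (L.MH_TEAM, L.CRISIS_SWS),
}
ORACLE_2B = {
    (Severity.NONE, False): (L.SELF_GUIDED, L.SELF_GUIDED),
    (Severity.NONE, True): (L.SELF_GUIDED, L.SELF_GUIDED),
    (Severity.MODERATE, False): (L.COUNSELING, L.COUNSELING),
    (Severity.MODERATE, True): (L.COUNSELING, L.PRIMARY_CARE),
    (Severity.SEVERE, False): (L.PRIMARY_CARE, L.MH_TEAM),
    (Severity.SEVERE, True): (L.MH_TEAM, L.MH_TEAM),
    (Severity.VERY_SEVERE, False): (L.MH_TEAM, L.MH_TEAM),
    (Severity.VERY_SEVERE, True): (L.MH_TEAM, L.CRISIS_SWS),
}
ORACLE_2C = {
    (Severity.NONE, False): (L.SELF_GUIDED, L.SELF_GUIDED),
    (Severity.NONE, True): (L.SELF_GUIDED, L.SELF_GUIDED),
    (Severity.MODERATE, False): (L.COUNSELING, L.COUNSELING),
    (Severity.MODERATE, True): (L.COUNSELING, L.PRIMARY_CARE),
    (Severity.SEVERE, False): (L.PRIMARY_CARE, L.MH_TEAM),
    (Severity.SEVERE, True): (L.MH_TEAM, L.MH_TEAM),
    (Severity.VERY_SEVERE, False): (L.MH_TEAM, L.ADDICTION_SERVICES),
    (Severity.VERY_SEVERE, True): (L.ADDICTION_SERVICES, L.CRISIS_SWS),
}


def oracle_engine_range(
    band: Severity,
    flag: bool,              # impairment or stress
    lifetime_history: bool,
    substance: bool,
    lifetime_suicidality: bool,   # attempt or self-harm
    current_item9: bool,
    severe_debilitating: bool,
    ml_positive: bool = False,
) -> tuple[CareLevel, CareLevel]:
    """Final care-level range by direct case analysis of the workflow."""
    # level 1 urgency
    if lifetime_suicidality and current_item9:
        return (L.URGENT_IN_PERSON, L.URGENT_IN_PERSON)
    if (lifetime_suicidality or current_item9) and (
        severe_debilitating or substance
    ):
        return (L.URGENT_IN_PERSON, L.URGENT_IN_PERSON)
    # 2a short-circuits the parallel stage
    if band != Severity.NONE:
        return ORACLE_2A[(band, flag)]
    candidates = []
    if lifetime_history:
        candidates.append(ORACLE_2B[(band, flag)])
    if substance:
        candidates.append(ORACLE_2C[(band, flag)])
    if ml_positive:
        candidates.append((L.SELF_GUIDED, L.SELF_GUIDED))
    if not candidates:
        return (L.NONE, L.NONE)
    return max(candidates, key=lambda r: (r[1], r[0]))


def oracle_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Metric formulas written out literally."""
    def div(a, b):
        return a / b if b else None

    sens = div(tp, tp + fn)
    spec = div(tn, tn + fp)
    ppv = div(tp, tp + fp)
    npv = div(tn, tn + fn)

    def f1(p, r):
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    f1_pos, f1_neg = f1(ppv, sens), f1(npv, spec)
    return {
        "accuracy": div(tp + tn, tp + fp + tn + fn),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f1_positive": f1_pos,
        "f1_macro": None if (f1_pos is None or f1_neg is None)
        else (f1_pos + f1_neg) / 2,
    }


def oracle_confusion(labels, scores, threshold) -> tuple[int, int, int, int]:
    """Plain-loop tabulation."""
    tp = fp = tn = fn = 0
    for y, s in zip(labels, scores):
        pred = s >= threshold
        if pred and y == 1:
            tp += 1
        elif pred and y == 0:
            fp += 1
        elif not pred and y == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def all_care_ranges() -> list[tuple[CareLevel, CareLevel]]:
    levels = list(CareLevel)
    return [(lo, hi) for lo, hi in product(levels, levels) if lo <= hi]
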