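import numpy as np
import pandas as pd
import pytest

from steppedcare.instruments import (
    BINARY_VARS,
    GAD7_ITEMS,
    HistoryFlags,
    PHQ9_ITEMS,
    STRESS_ITEMS,
    SUBSTANCE_VARS,
    ScaleDictionary,
    ScoredProfile,
    Severity,
    SubstanceFlags,
)


@pytest.fixture(scope="session")
def dictionary() -> ScaleDictionary:
    return ScaleDictionary.default()


def make_raw_row(**overrides) -> dict:
    """A fully negative raw-coded survey row; override fields per test."""
    row: dict = {"student_id": "S1", "term_index": 1}
    for v in PHQ9_ITEMS + GAD7_ITEMS:
        row[v] = 0
    row["PHQ9_DIFF_1"] = 0
    row["GAD7_DIFF_1"] = 0
    # neutral stress answers: no clause fires
    row["STRESS_1_1"], row["STRESS_2_1"] = 2, 2
    row["STRESS_3_1"], row["STRESS_4_1"] = 3, 2
    for v in BINARY_VARS:
        row[v] = 2          # raw coding: 2 = No
    for v in SUBSTANCE_VARS:
        row[v] = 0
    row.update(overrides)
    return row


def make_profile(
    band: Severity = Severity.NONE,
    impairment: bool = False,
    stress: bool = False,
    lifetime_history: bool = False,
    substance: bool = False,
    attempt: bool = False,
    self_harm: bool = False,
    item9: int = 0,
    phq9_total: int | None = None,
) -> ScoredProfile:
    """Directly constructed profile for rule-lattice tests."""
    totals = {
        Severity.NONE: 0,
        Severity.MODERATE: 12,
        Severity.SEVERE: 16,
        Severity.VERY_SEVERE: 21,
    }
    phq = totals[band] if phq9_total is None else phq9_total
    return ScoredProfile(
        student_id="P",
        phq9_total=phq,
        gad7_total=0,
        phq2_total=min(phq, 6),
        gad2_total=0,
        band=band,
        impairment=impairment,
        stress=stress,
        history=HistoryFlags(
            lifetime_history=lifetime_history,
            family={}, adversity={},
            wish_dead=False, ideation=False,
            attempt=attempt, self_harm=self_harm,
        ),
        substances=SubstanceFlags(
            binge=substance, cannabis=False, any_other_drug=False
        ),
        phq9_item9=item9,
    )


@pytest.fixture()
def raw_cohort_frame() -> pd.DataFrame:
    rows = [make_raw_row(student_id=f"S{i}") for i in range(4)]
    return pd.DataFrame(rows)
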