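"""Level 1 urgency, level 2 rule tables, combination, and engine routing."""

from itertools import product

import pytest

from steppedcare.instruments import Severity
from steppedcare.rules import (
    CareLevel,
    Recommendation,
    RuleThresholds,
    SourceRule,
    combine_recommendations,
    evaluate_level1,
    evaluate_level2a,
    evaluate_level2b,
    evaluate_level2c,
    run_engine,
)

from conftest import make_profile
from oracles import all_care_ranges, oracle_engine_range

L = CareLevel


class TestLevel1:
    def test_both_lifetime_and_current_is_urgent(self):
        p = make_profile(attempt=True, item9=2)
        out = evaluate_level1(p)
        assert out.urgent
        assert out.recommendation.high == L.URGENT_IN_PERSON

    def test_all_negative_is_not_urgent(self):
        assert not evaluate_level1(make_profile()).urgent

    def test_lifetime_alone_without_additional_threshold_not_urgent(self):
        p = make_profile(self_harm=True, item9=0, phq9_total=8)
        assert not evaluate_level1(p).urgent

    def test_lifetime_alone_with_substance_use_is_urgent(self):
        p = make_profile(self_harm=True, substance=True)
        assert evaluate_level1(p).urgent

    def test_current_alone_with_severe_debilitating_depression_is_urgent(self):
        p = make_profile(band=Severity.VERY_SEVERE, impairment=True, item9=1)
        assert evaluate_level1(p).urgent
        # same symptoms without impairment: not severe-debilitating
        q = make_profile(band=Severity.VERY_SEVERE, impairment=False, item9=1)
        assert not evaluate_level1(q).urgent

    def test_ideation_switch_widens_lifetime_screen(self):
        # wish-dead counts as a lifetime positive only under the config switch
        import dataclasses

        from steppedcare.instruments import SubstanceFlags

        p = make_profile(item9=1)
        hist = dataclasses.replace(p.history, wish_dead=True, attempt=False,
                                   self_harm=False)
        p2 = dataclasses.replace(
            p, history=hist, phq9_item9=0,
            substances=SubstanceFlags(True, False, False))
        assert not evaluate_level1(p2).urgent
        cfg = RuleThresholds(include_ideation_in_level1=True)
        assert evaluate_level1(p2, cfg).urgent


class TestLevel2Tables:
    def test_2a_requires_at_least_moderate_symptoms(self):
        assert evaluate_level2a(make_profile(band=Severity.NONE)) is None

    @pytest.mark.parametrize(
        "band, flag, expected",
        [
            (Severity.MODERATE, False, (L.SELF_GUIDED, L.COUNSELING)),
            (Severity.VERY_SEVERE, True, (L.MH_TEAM, L.CRISIS_SWS)),
            (Severity.SEVERE, False, (L.COUNSELING, L.PRIMARY_CARE)),
        ],
    )
    def test_2a_cells(self, band, flag, expected):
        rec = evaluate_level2a(make_profile(band=band, stress=flag))
        assert (rec.low, rec.high) == expected
        assert rec.source_rule == SourceRule.L2A

    def test_2b_history_alone_gets_self_guided(self):
        rec = evaluate_level2b(make_profile(lifetime_history=True))
        assert (rec.low, rec.high) == (L.SELF_GUIDED, L.SELF_GUIDED)

    def test_2b_without_history_is_silent(self):
        assert evaluate_level2b(make_profile(band=Severity.SEVERE)) is None

    def test_2b_severe_with_impairment(self):
        rec = evaluate_level2b(
            make_profile(band=Severity.SEVERE, impairment=True,
                         lifetime_history=True))
        assert (rec.low, rec.high) == (L.MH_TEAM, L.MH_TEAM)

    def test_2c_substance_alone_gets_self_guided(self):
        rec = evaluate_level2c(make_profile(substance=True))
        assert (rec.low, rec.high) == (L.SELF_GUIDED, L.SELF_GUIDED)
        assert "binge_drinking" in rec.rationale

    def test_2c_without_substance_is_silent(self):
        assert evaluate_level2c(make_profile(band=Severity.MODERATE)) is None

    def test_2c_very_severe_with_stress_escalates_to_addiction_services(self):
        rec = evaluate_level2c(
            make_profile(band=Severity.VERY_SEVERE, stress=True, substance=True))
        assert (rec.low, rec.high) == (L.ADDICTION_SERVICES, L.CRISIS_SWS)


def _rec(low, high, source=SourceRule.L2A):
    rationale = () if high == L.NONE else ("clause",)
    return Recommendation(low, high, source, rationale)


class TestCombine:
    def test_highest_level_wins(self):
        out = combine_recommendations([
            _rec(L.SELF_GUIDED, L.SELF_GUIDED, SourceRule.L2B),
            _rec(L.COUNSELING, L.PRIMARY_CARE, SourceRule.L2A),
        ])
        assert (out.low, out.high) == (L.COUNSELING, L.PRIMARY_CARE)

    def test_single_input_is_identity(self):
        r = _rec(L.MH_TEAM, L.MH_TEAM)
        assert combine_recommendations([r]) == r

    def test_tie_on_high_resolved_by_low(self):
        out = combine_recommendations([
            _rec(L.MH_TEAM, L.MH_TEAM, SourceRule.L2C),
            _rec(L.PRIMARY_CARE, L.MH_TEAM, SourceRule.L2B),
        ])
        assert (out.low, out.high) == (L.MH_TEAM, L.MH_TEAM)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_recommendations([])

    def test_exhaustive_pairs_match_max_semantics(self):
        # commutative and idempotent over every pair of care ranges
        ranges = all_care_ranges()
        for a, b in product(ranges, ranges):
            ra = _rec(*a, SourceRule.L2B)
            rb = _rec(*b, SourceRule.L2C)
            ab = combine_recommendations([ra, rb])
            ba = combine_recommendations([rb, ra])
            assert (ab.low, ab.high) == (ba.low, ba.high)
            assert (ab.low, ab.high) == max(a, b, key=lambda r: (r[1], r[0]))
            aa = combine_recommendations([ra, ra])
            assert (aa.low, aa.high) == a

    def test_associative_up_to_tiebreak(self):
        ranges = all_care_ranges()[::3]
        for a, b, c in product(ranges, ranges, ranges):
            recs = [_rec(*a, SourceRule.L2A), _rec(*b, SourceRule.L2B),
                    _rec(*c, SourceRule.L2C)]
            left = combine_recommendations(
                [combine_recommendations(recs[:2]), recs[2]])
            right = combine_recommendations(
                [recs[0], combine_recommendations(recs[1:])])
            assert (left.low, left.high) == (right.low, right.high)


class TestEngine:
    def test_symptomatic_student_stops_at_2a(self):
        out = run_engine(make_profile(band=Severity.MODERATE))
        assert out.stage_reached == SourceRule.L2A
        assert out.fired == (SourceRule.L2A,)

    def test_all_negative_with_ml_risk_gets_self_guided(self):
        out = run_engine(make_profile(), ml_positive=True)
        assert (out.final.low, out.final.high) == (L.SELF_GUIDED, L.SELF_GUIDED)
        assert out.final.source_rule == SourceRule.ML

    def test_all_negative_without_ml_gets_no_recommendation(self):
        out = run_engine(make_profile(), ml_positive=False)
        assert out.final.high == L.NONE
        assert out.stage_reached == SourceRule.NONE

    def test_urgent_short_circuits_everything(self):
        out = run_engine(make_profile(attempt=True, item9=1, band=Severity.SEVERE))
        assert out.urgent and out.final.high == L.URGENT_IN_PERSON

    def test_engine_matches_brute_force_over_full_lattice(self):
        cfg = RuleThresholds()
        bands = list(Severity)
        bools = (False, True)
        for band, impair, stress, hist, subst, attempt, item9, ml in product(
            bands, bools, bools, bools, bools, bools, (0, 1), bools
        ):
            p = make_profile(
                band=band, impairment=impair, stress=stress,
                lifetime_history=hist, substance=subst, attempt=attempt,
                item9=item9,
            )
            got = run_engine(p, cfg, ml_positive=ml)
            severe_deb = p.phq9_total >= 20 and impair
            want = oracle_engine_range(
                band, impair or stress, hist, subst, attempt, item9 >= 1,
                severe_deb, ml,
            )
            assert (got.final.low, got.final.high) == want, (
                band, impair, stress, hist, subst, attempt, item9, ml
            )

    def test_raising_band_or_flags_never_lowers_final_high(self):
        cfg = RuleThresholds()
        bands = list(Severity)
        bools = (False, True)
        for band, impair, stress, hist, subst in product(
            bands[:-1], bools, bools, bools, bools
        ):
            base = run_engine(make_profile(
                band=band, impairment=impair, stress=stress,
                lifetime_history=hist, substance=subst))
            higher = run_engine(make_profile(
                band=Severity(band + 1), impairment=impair, stress=stress,
                lifetime_history=hist, substance=subst))
            assert higher.final.high >= base.final.high
            for kw in ("impairment", "stress", "lifetime_history", "substance"):
                kwargs = dict(band=band, impairment=impair, stress=stress,
                              lifetime_history=hist, substance=subst)
                if kwargs[kw]:
                    continue
                kwargs[kw] = True
                flagged = run_engine(make_profile(**kwargs))
                assert flagged.final.high >= base.final.high

    def test_determinism(self):
        p = make_profile(band=Severity.SEVERE, stress=True, substance=True)
        assert run_engine(p) == run_engine(p)

    def test_l2bc_on_all_flag_keeps_2a_students_in_parallel_stage(self):
        cfg = RuleThresholds(evaluate_l2bc_on_all=True)
        p = make_profile(band=Severity.MODERATE, substance=True)
        out = run_engine(p, cfg)
        assert SourceRule.L2C in out.fired and SourceRule.L2A in out.fired


class TestThresholdConfig:
    def test_json_round_trip(self):
        cfg = RuleThresholds(evaluate_l2bc_on_all=True)
        back = RuleThresholds.from_json(cfg.to_json())
        assert back.table_2a == cfg.table_2a
        assert back.table_2c == cfg.table_2c
        assert back.evaluate_l2bc_on_all
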