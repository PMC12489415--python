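"""ML cohort selection, feature/label construction, splitting, and training."""

import numpy as np
import pandas as pd
import pytest

from steppedcare.instruments import GAD7_ITEMS_T2, PHQ9_ITEMS_T2, decode_raw
from steppedcare.models import (
    LabeledCohort,
    ModelVariant,
    RiskModel,
    build_features,
    classify_risk,
    feature_columns,
    predict_risk,
    select_ml_cohort,
    split_stratified,
    train_model,
)
from steppedcare.simulate import CohortConfig, generate_cohort, label_followup

from conftest import make_raw_row


@pytest.fixture(scope="module")
def decoded_cohort():
    cfg = CohortConfig(n=900, seed=17)
    return decode_raw(label_followup(generate_cohort(cfg), cfg))


def _with_t2(row: dict, phq_items=None, gad_items=None) -> dict:
    row = dict(row)
    for i, name in enumerate(PHQ9_ITEMS_T2):
        row[name] = (phq_items or [0] * 9)[i]
    for i, name in enumerate(GAD7_ITEMS_T2):
        row[name] = (gad_items or [0] * 7)[i]
    return row


class TestCohortSelection:
    def test_urgent_and_symptomatic_students_are_excluded(self, dictionary):
        rows = [
            # urgent: lifetime attempt + current item 9
            _with_t2(make_raw_row(student_id="urgent", SUICATMP_1=1, PHQ9_9_1=2)),
            # level 2a: moderate symptoms (PHQ-9 total 12)
            _with_t2(make_raw_row(
                student_id="moderate",
                **{f"PHQ9_{i}_1": 2 for i in range(1, 7)})),
            # eligible: all negative with follow-up
            _with_t2(make_raw_row(student_id="eligible")),
        ]
        decoded = decode_raw(pd.DataFrame(rows), dictionary)
        kept = select_ml_cohort(decoded)
        assert list(kept["student_id"]) == ["eligible"]

    def test_students_without_followup_are_excluded(self, dictionary):
        complete = _with_t2(make_raw_row(student_id="with"))
        incomplete = _with_t2(make_raw_row(student_id="without"))
        incomplete["PHQ9_1_2"] = np.nan
        decoded = decode_raw(pd.DataFrame([complete, incomplete]), dictionary)
        kept = select_ml_cohort(decoded)
        assert list(kept["student_id"]) == ["with"]

    def test_empty_selection_raises(self, dictionary):
        row = _with_t2(make_raw_row(SUICATMP_1=1, PHQ9_9_1=2))
        decoded = decode_raw(pd.DataFrame([row]), dictionary)
        with pytest.raises(ValueError, match="larger cohort"):
            select_ml_cohort(decoded)


class TestFeaturesAndLabels:
    def test_abbreviated_variant_drops_later_symptom_items(self):
        cols = feature_columns(ModelVariant("depression", "abbreviated"))
        assert "PHQ9_1_1" in cols and "GAD7_2_1" in cols
        assert all(f"PHQ9_{i}_1" not in cols for i in range(3, 10))
        assert all(f"GAD7_{i}_1" not in cols for i in range(3, 8))
        assert "PHQ9_DIFF_1" in cols and "GAD7_DIFF_1" in cols

    def test_labels_follow_time2_cutoff(self, dictionary):
        pos = _with_t2(make_raw_row(student_id="pos"),
                       phq_items=[2, 2, 2, 2, 2, 0, 0, 0, 0])   # total 10
        neg = _with_t2(make_raw_row(student_id="neg"),
                       gad_items=[2, 2, 2, 2, 1, 0, 0])          # total 9
        decoded = decode_raw(pd.DataFrame([pos, neg]), dictionary)
        dep = build_features(decoded, ModelVariant("depression", "full"))
        anx = build_features(decoded, ModelVariant("anxiety", "full"))
        assert dep.y.tolist() == [1, 0]
        assert anx.y.tolist() == [0, 0]

    def test_labels_match_independent_oracle(self, decoded_cohort):
        cohort = build_features(decoded_cohort, ModelVariant("anxiety", "full"))
        oracle = (
            decoded_cohort[list(GAD7_ITEMS_T2)].to_numpy().sum(axis=1) >= 10
        ).astype(int)
        np.testing.assert_array_equal(cohort.y, oracle)

    def test_no_time2_columns_leak_into_features(self):
        for variant in (ModelVariant("depression", "full"),
                        ModelVariant("anxiety", "abbreviated")):
            assert not any(c.endswith("_2") for c in feature_columns(variant))

    def test_missing_feature_column_is_named(self, decoded_cohort):
        broken = decoded_cohort.drop(columns=["BULLYING_1"])
        with pytest.raises(ValueError, match="BULLYING_1"):
            build_features(broken, ModelVariant("depression", "full"))


class TestSplit:
    def _toy(self, n=100, pos=20):
        X = pd.DataFrame({"x": np.arange(n, dtype=float)})
        y = np.array([1] * pos + [0] * (n - pos))
        return LabeledCohort(X=X, y=y, ids=pd.RangeIndex(n))

    def test_stratification_arithmetic(self):
        train, test = split_stratified(self._toy(), ratio=0.7, seed=0)
        assert len(train.y) == 70 and len(test.y) == 30
        assert train.y.sum() == 14 and test.y.sum() == 6

    def test_partition_is_disjoint_and_exhaustive(self):
        cohort = self._toy()
        train, test = split_stratified(cohort, seed=1)
        ids = set(train.X["x"]) | set(test.X["x"])
        assert len(ids) == 100
        assert not (set(train.X["x"]) & set(test.X["x"]))

    def test_same_seed_same_split(self):
        a_train, _ = split_stratified(self._toy(), seed=5)
        b_train, _ = split_stratified(self._toy(), seed=5)
        pd.testing.assert_frame_equal(a_train.X, b_train.X)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            split_stratified(self._toy(pos=1))


class TestTraining:
    @pytest.fixture(scope="class")
    def train_cohort(self, decoded_cohort):
        variant = ModelVariant("depression", "full")
        cohort = build_features(select_ml_cohort(decoded_cohort), variant)
        train, test = split_stratified(cohort, seed=2)
        return variant, train, test

    def test_single_point_grid_is_chosen(self, train_cohort):
        variant, train, _ = train_cohort
        model = train_model(train, variant, grid=[2.5], cv_folds=3, seed=0,
                            n_estimators=30)
        assert model.scale_pos_weight == 2.5

    def test_training_is_deterministic(self, train_cohort):
        variant, train, _ = train_cohort
        a = train_model(train, variant, cv_folds=3, seed=4, n_estimators=30)
        b = train_model(train, variant, cv_folds=3, seed=4, n_estimators=30)
        assert a.threshold == b.threshold
        assert a.scale_pos_weight == b.scale_pos_weight
        pd.testing.assert_frame_equal(a.cv_table, b.cv_table)
        assert (a.estimator.get_booster().save_raw()
                == b.estimator.get_booster().save_raw())

    def test_training_never_sees_test_data(self, train_cohort):
        # permuting test labels cannot change the fitted model
        variant, train, test = train_cohort
        a = train_model(train, variant, cv_folds=3, seed=4, n_estimators=30)
        rng = np.random.default_rng(0)
        _ = rng.permutation(test.y)   # "use" of test labels happens outside
        b = train_model(train, variant, cv_folds=3, seed=4, n_estimators=30)
        assert (a.estimator.get_booster().save_raw()
                == b.estimator.get_booster().save_raw())

    def test_separable_planted_signal_reaches_high_cv_f1(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
        y = (x > 0.4).astype(int)
        cohort = LabeledCohort(X=X, y=y, ids=pd.RangeIndex(n))
        model = train_model(cohort, ModelVariant("depression", "full"),
                            cv_folds=5, seed=0, n_estimators=60)
        assert model.cv_table.groupby("scale_pos_weight")["macro_f1"].mean().max() >= 0.95

    def test_threshold_meets_target_on_oof_predictions(self, train_cohort):
        variant, train, _ = train_cohort
        model = train_model(train, variant, cv_folds=5, seed=1,
                            target_sensitivity=0.9, n_estimators=30)
        assert 0 < model.threshold < 1

    def test_predictions_and_boundaries(self, train_cohort):
        variant, train, test = train_cohort
        model = train_model(train, variant, cv_folds=3, seed=0, n_estimators=30)
        p = predict_risk(model, test.X)
        assert ((p >= 0) & (p <= 1)).all()
        model_all = RiskModel(**{**model.__dict__, "threshold": 0.0})
        assert classify_risk(model_all, test.X).all()
        model_none = RiskModel(**{**model.__dict__, "threshold": 1.0})
        assert not classify_risk(model_none, test.X).any()

    def test_feature_order_mismatch_is_named(self, train_cohort):
        variant, train, test = train_cohort
        model = train_model(train, variant, cv_folds=3, seed=0, n_estimators=30)
        shuffled = test.X[list(test.X.columns[::-1])]
        with pytest.raises(ValueError, match="feature columns"):
            predict_risk(model, shuffled)

    def test_save_load_round_trip(self, train_cohort, tmp_path):
        variant, train, test = train_cohort
        model = train_model(train, variant, cv_folds=3, seed=0, n_estimators=30)
        model.save(tmp_path / "bundle")
        loaded = RiskModel.load(tmp_path / "bundle")
        assert loaded.threshold == model.threshold
        assert loaded.feature_names == model.feature_names
        np.testing.assert_allclose(
            predict_risk(loaded, test.X), predict_risk(model, test.X),
            rtol=1e-6,
        )
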