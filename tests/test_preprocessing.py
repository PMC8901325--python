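"""QC filtering, bilinear resizing, clinical cleaning/encoding and the
stratified split."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermofusion import (
    ClinicalEncoder,
    ClinicalRecord,
    SplitSpec,
    SyntheticConfig,
    clean_clinical,
    encode_clinical,
    generate_cohort,
    inject_defect,
    qc_filter,
    resize_square,
    split_assignments,
    stratified_split,
)
from thermofusion.synthetic import VIEW_LABELS


def _record(pid="P1", age=45.0, menarche=13.0, diagnosis="healthy", **discrete):
    base = {"smoking_habit": "no", "symptoms": "no"}
    base.update(discrete)
    return ClinicalRecord(
        patient_id=pid, discrete=base,
        continuous={"age_at_screening": age, "menarche_age": menarche},
        diagnosis=diagnosis,
    )


class TestQCFilter:
    def test_clean_cohort_is_untouched(self, small_cohort):
        _, studies, _ = small_cohort
        kept, report = qc_filter(studies[:10], VIEW_LABELS)
        assert len(kept) == 10 and report.removed == {}

    def test_blurry_without_substitute_removed_with_reason(self, clean_study):
        bad = inject_defect(clean_study, "blurry", seed=1)
        kept, report = qc_filter([bad], VIEW_LABELS)
        assert kept == []
        assert report.removed[bad.patient_id] == "blurry"

    def test_missing_view_removed(self, clean_study):
        bad = inject_defect(clean_study, "missing_view", seed=1)
        _, report = qc_filter([bad], VIEW_LABELS)
        assert report.removed[bad.patient_id] == "missing_views"

    def test_dynamic_counterpart_substituted_not_removed(self, clean_study):
        bad = inject_defect(clean_study, "blurry", seed=1)
        view = bad.defect_views["blurry"]
        bad.dynamic_views[view] = clean_study.views[view].copy()
        kept, report = qc_filter([bad], VIEW_LABELS)
        assert len(kept) == 1
        assert report.substitutions[(bad.patient_id, view)] == "static->dynamic"
        assert kept[0].protocol[view] == "dynamic"
        np.testing.assert_array_equal(kept[0].views[view], clean_study.views[view])

    def test_injected_defect_count_matches_removals(self):
        # force a blur on every patient, no dynamic backups -> all removed
        config = SyntheticConfig(n_healthy=6, n_sick=6, image_height=32,
                                 image_width=32, seed=3,
                                 defect_rates={"blurry": 1.0},
                                 dynamic_backup_rate=0.0)
        studies, _ = generate_cohort(config)
        k = sum("blurry" in s.qc_flags for s in studies)
        _, report = qc_filter(studies, VIEW_LABELS)
        assert k == 12 and len(report.removed) == k

    def test_idempotent(self, small_cohort):
        _, studies, _ = small_cohort
        mixed = [inject_defect(studies[0], "injury", seed=2), *studies[1:6]]
        once, r1 = qc_filter(mixed, VIEW_LABELS)
        twice, r2 = qc_filter(once, VIEW_LABELS)
        assert [s.patient_id for s in once] == [s.patient_id for s in twice]
        assert r2.removed == {}

    def test_blur_on_unrequired_view_kept(self, clean_study):
        bad = inject_defect(clean_study, "blurry", seed=1)
        view = bad.defect_views["blurry"]
        required = set(VIEW_LABELS) - {view}
        kept, _ = qc_filter([bad], required)
        assert len(kept) == 1

    def test_empty_required_views_rejected(self):
        with pytest.raises(ValueError, match="required_views"):
            qc_filter([], set())


class TestResizeSquare:
    def test_aspect_change_640x480(self):
        out = resize_square(np.random.default_rng(0).normal(size=(480, 640)), 640)
        assert out.shape == (640, 640)

    def test_constant_input_constant_output(self):
        out = resize_square(np.full((480, 640), 33.5), 64)
        np.testing.assert_allclose(out, 33.5)

    def test_matches_hand_computed_bilinear(self):
        # rows align exactly (4 -> 4); columns sample at 0, 1/3, 2/3, 1
        m = np.array([[0.0, 3.0], [6.0, 9.0], [12.0, 15.0], [30.0, 33.0]])
        expected = np.array([
            [a + 3.0 * t for t in (0, Fraction(1, 3), Fraction(2, 3), 1)]
            for a in (0.0, 6.0, 12.0, 30.0)
        ], dtype=float)
        np.testing.assert_allclose(resize_square(m, 4), expected, atol=1e-12)

    def test_output_range_within_input_range(self, rng):
        m = rng.normal(size=(17, 29))
        out = resize_square(m, 40)
        assert out.min() >= m.min() - 1e-12 and out.max() <= m.max() + 1e-12

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            resize_square(np.ones((1, 5)), 8)


class TestCleanClinical:
    def test_age_anomalies_removed(self):
        records = [
            _record("P1", age=0.0),
            _record("P2", age=120.0),
            _record("P3", age=45.0),
        ]
        cleaned, report = clean_clinical(records)
        assert [r.patient_id for r in cleaned] == ["P3"]
        assert report.removed == {"P1": "age_anomaly", "P2": "age_anomaly"}

    def test_blank_discrete_filled_with_not_answered(self):
        cleaned, _ = clean_clinical([_record("P1", smoking_habit="")])
        assert cleaned[0].discrete["smoking_habit"] == "not answered"

    def test_missing_menarche_imputed_with_median(self):
        records = [
            _record("P1", menarche=11.0),
            _record("P2", menarche=15.0),
            _record("P3", menarche=12.0),
            _record("P4", menarche=None),
        ]
        cleaned, _ = clean_clinical(records)
        assert cleaned[3].continuous["menarche_age"] == 12.0

    def test_precomputed_median_applies_without_refit(self):
        cleaned, _ = clean_clinical([_record("P1", menarche=None)], menarche_median=14.0)
        assert cleaned[0].continuous["menarche_age"] == 14.0


class TestClinicalEncoder:
    def _toy_records(self):
        cats = [("a", "x", "u"), ("b", "y", "v"), ("a", "z", "w"), ("b", "x", "t")]
        return [
            ClinicalRecord(
                patient_id=f"P{i}",
                discrete={"f2": c2, "f3": c3, "f4": c4},
                continuous={"age_at_screening": float(a), "menarche_age": float(m)},
                diagnosis="healthy" if i % 2 else "sick",
            )
            for i, ((c2, c3, c4), a, m) in enumerate(
                zip(cats, (2, 4, 6, 4), (11, 12, 13, 14)))
        ]

    def test_onehot_width_counts_categories(self):
        # 3 discrete features with {2, 3, 4} observed categories + 2 continuous
        enc = ClinicalEncoder(discrete_features=("f2", "f3", "f4"))
        enc.fit(self._toy_records())
        assert len(enc.feature_names_) == 2 + 3 + 4 + 2

    def test_minmax_definition_and_constant_column(self):
        records = [_record(f"P{i}", age=a, menarche=13.0) for i, a in enumerate((2, 4, 6))]
        enc = ClinicalEncoder(discrete_features=("smoking_habit",)).fit(records)
        X = enc.transform(records)
        np.testing.assert_allclose(X[:, -2], [0.0, 0.5, 1.0])  # age column
        np.testing.assert_allclose(X[:, -1], 0.0)  # constant menarche -> 0

    def test_unseen_category_maps_to_zero_block(self):
        enc = ClinicalEncoder(discrete_features=("f2", "f3", "f4"))
        records = self._toy_records()
        enc.fit(records)
        novel = records[0].copy()
        novel.discrete["f3"] = "never-seen"
        X = enc.transform([novel])
        f3_cols = [i for i, n in enumerate(enc.feature_names_) if n.startswith("f3_")]
        assert X[0, f3_cols].sum() == 0.0

    def test_no_leakage_from_test_partition(self):
        records = [_record(f"P{i}", age=20.0 + i) for i in range(6)]
        enc = ClinicalEncoder(discrete_features=("smoking_habit",)).fit(records[:4])
        params_before = (enc.scaler_.data_min_.copy(), enc.scaler_.data_max_.copy())
        X_train = enc.transform(records[:4])
        X_test = enc.transform(records[4:])  # ages beyond the training range
        assert X_train[:, -2].min() >= 0.0 and X_train[:, -2].max() <= 1.0
        assert X_test[:, -2].max() > 1.0  # out-of-range, not clipped, not refit
        np.testing.assert_array_equal(enc.scaler_.data_min_, params_before[0])
        np.testing.assert_array_equal(enc.scaler_.data_max_, params_before[1])

    def test_encode_clinical_labels(self):
        enc = encode_clinical([_record("P1", diagnosis="sick"), _record("P2")])
        np.testing.assert_array_equal(enc.label_vector, [1, 0])
        assert enc.matrix.shape[0] == 2

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            encode_clinical([])


class TestStratifiedSplit:
    @pytest.mark.parametrize("n,expected", [
        (157, (126, 31)),  # screening cohort, healthy class
        (84, (67, 17)),    # sick class
        (10, (8, 2)),
    ])
    def test_eighty_twenty_counts(self, n, expected):
        assert stratified_split({"c": n})["c"] == expected

    def test_round_half_up_exhaustive(self):
        for n in range(0, 501):
            train, test = stratified_split({"c": n})["c"]
            assert test == int(np.floor(0.2 * n + 0.5))
            assert train + test == n and train >= 0 and test >= 0

    def test_assignment_partitions_cohort(self):
        ids = {"healthy": [f"h{i}" for i in range(157)],
               "sick": [f"s{i}" for i in range(84)]}
        assignment = split_assignments(ids, SplitSpec(seed=3))
        assert len(assignment) == 241
        test_h = sum(1 for p, part in assignment.items()
                     if part == "test" and p.startswith("h"))
        test_s = sum(1 for p, part in assignment.items()
                     if part == "test" and p.startswith("s"))
        assert (test_h, test_s) == (31, 17)

    def test_seeded_assignment_reproducible(self):
        ids = {"c": [f"p{i}" for i in range(20)]}
        a = split_assignments(ids, SplitSpec(seed=9))
        b = split_assignments(ids, SplitSpec(seed=9))
        assert a == b

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="test_fraction"):
            SplitSpec(test_fraction=1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(0, 2000), frac=st.floats(0.05, 0.95))
    def test_split_counts_always_partition(self, n, frac):
        train, test = stratified_split({"c": n}, SplitSpec(test_fraction=frac))["c"]
        assert train + test == n and 0 <= test <= n
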