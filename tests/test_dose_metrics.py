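"""Per-exam metrics, patient accumulation, and the inclusion filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctrisk as ck
from ctrisk.dose_metrics import (
    ConsistencyError,
    UndefinedFactorError,
    compute_exam_metrics_frame,
    validate_exam_frame,
)
from ctrisk.reference_data import VocabularyError


def make_exam(sex="female", age=50.0, region="chest", dlp=100.0, **doses):
    return ck.ExamRecord(
        patient_id="P1", sex=sex, age_at_exam=age, region=region, dlp=dlp,
        organ_doses=doses,
    )


class TestEDLP:
    @pytest.mark.parametrize(
        "dlp,region,expected",
        [(1000.0, "chest", 14.0), (0.0, "head", 0.0), (500.0, "abdomen", 7.5)],
    )
    def test_dlp_times_k(self, tables, dlp, region, expected):
        exam = make_exam(region=region, dlp=dlp)
        assert ck.compute_e_dlp(exam, tables.dlp) == pytest.approx(expected)

    def test_unknown_region(self, tables):
        with pytest.raises(VocabularyError):
            ck.compute_e_dlp(make_exam(region="xyz"), tables.dlp)


class TestEOD:
    def test_uniform_dose_gives_that_dose(self, tables, uniform_exam):
        # sum of ICRP 103 weights over one person's tissues is 1
        assert ck.compute_e_od(uniform_exam, tables.tissue_weights) == pytest.approx(
            10.0, abs=1e-9
        )

    def test_lung_only(self, tables):
        exam = make_exam(lung=10.0)
        assert ck.compute_e_od(exam, tables.tissue_weights) == pytest.approx(1.2)

    def test_zero_vector(self, tables):
        exam = make_exam(lung=0.0, liver=0.0)
        assert ck.compute_e_od(exam, tables.tissue_weights) == 0.0

    def test_gonad_organ_uses_gonad_weight(self, tables):
        exam = make_exam(ovaries=10.0)
        assert ck.compute_e_od(exam, tables.tissue_weights) == pytest.approx(0.8)

    def test_unknown_organ(self, tables):
        with pytest.raises(VocabularyError):
            ck.compute_e_od(make_exam(eyeball=1.0), tables.tissue_weights)


class TestRI:
    def test_zero_doses(self, tables):
        assert ck.compute_ri(make_exam(lung=0.0), tables.lar, tables.site_map) == 0.0

    def test_linearity_in_dose(self, tables, chest_exam):
        ri1 = ck.compute_ri(chest_exam, tables.lar, tables.site_map)
        doubled = ck.ExamRecord(
            patient_id=chest_exam.patient_id,
            sex=chest_exam.sex,
            age_at_exam=chest_exam.age_at_exam,
            region=chest_exam.region,
            dlp=chest_exam.dlp,
            organ_doses={o: 2 * d for o, d in chest_exam.organ_doses.items()},
        )
        assert ck.compute_ri(doubled, tables.lar, tables.site_map) == pytest.approx(
            2 * ri1, rel=1e-12
        )

    def test_single_organ_against_brute_force_coefficient_file(self, tables):
        """Independent oracle: interpolate the raw CSV directly with numpy."""
        from ctrisk.reference_data import _resource_path

        raw = pd.read_csv(_resource_path("beir7_lar_incidence.csv"))
        sub = raw[(raw.site == "colon") & (raw.sex == "male")].sort_values("age")
        age, dose = 47.0, 12.5
        expected = np.interp(age, sub.age, sub.value) / 100_000.0 * dose
        exam = make_exam(sex="male", age=age, colon=dose)
        assert ck.compute_ri(exam, tables.lar, tables.site_map) == pytest.approx(
            expected, rel=1e-12
        )

    def test_site_absent_for_sex_contributes_zero(self, tables):
        # breast dose in a male: no male breast coefficient in the LAR table
        exam = make_exam(sex="male", breast=15.0)
        assert ck.compute_ri(exam, tables.lar, tables.site_map) == 0.0


class TestRIRP:
    def test_zero_doses(self, tables):
        assert ck.compute_ri_rp(make_exam(), tables.lar, tables.site_map) == 0.0

    def test_linearity(self, tables, chest_exam):
        base = ck.compute_ri_rp(chest_exam, tables.lar, tables.site_map)
        scaled = ck.ExamRecord(
            patient_id="P1", sex=chest_exam.sex, age_at_exam=chest_exam.age_at_exam,
            region=chest_exam.region, dlp=chest_exam.dlp,
            organ_doses={o: 3 * d for o, d in chest_exam.organ_doses.items()},
        )
        assert ck.compute_ri_rp(scaled, tables.lar, tables.site_map) == pytest.approx(
            3 * base, rel=1e-12
        )

    def test_equals_ri_for_symmetric_table_at_35(self, tables):
        """With male = female coefficients and exam age 35, RI == RI_rp."""
        ages = tables.lar.tabulated_ages
        entries = {}
        for (site, sex), vals in tables.lar.entries.items():
            entries[(site, "male")] = vals
            entries[(site, "female")] = vals
        # drop sex-specific sites: symmetric table must cover both sexes
        for site in ("breast", "ovary", "uterus", "prostate"):
            entries.pop((site, "male"), None)
            entries.pop((site, "female"), None)
        sym = ck.LARTable(entries, ages)
        exam = make_exam(sex="male", age=35.0, lung=20.0, colon=5.0, stomach=3.0)
        ri = ck.compute_ri(exam, sym, tables.site_map)
        ri_rp = ck.compute_ri_rp(exam, sym, tables.site_map)
        assert ri == pytest.approx(ri_rp, rel=1e-12)


class TestFandER:
    def test_ratio(self):
        assert ck.compute_f(0.6, 1.2) == pytest.approx(0.5)

    def test_unity_when_equal(self):
        assert ck.compute_f(0.8, 0.8) == 1.0

    def test_zero_dose_defined_as_zero(self):
        assert ck.compute_f(0.0, 0.0) == 0.0

    def test_undefined_factor(self):
        with pytest.raises(UndefinedFactorError):
            ck.compute_f(0.5, 0.0)

    @pytest.mark.parametrize("f,e_od,expected", [(1.0, 42.0, 42.0), (0.5, 200.0, 100.0), (0.0, 7.0, 0.0)])
    def test_e_r_product(self, f, e_od, expected):
        assert ck.compute_e_r(f, e_od) == expected

    def test_metricset_identities_hold_for_computed_exam(self, tables, chest_exam):
        m = ck.compute_metrics(chest_exam, tables)
        m.check_exam_identities()  # raises on violation


class TestHomogeneity:
    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    def test_metrics_scale_linearly_with_dose(self, scale):
        """All six metrics are degree-1 homogeneous in dose; f is degree 0."""
        tables = ck.default_tables()
        template = ck.default_protocols()[0]
        base = ck.ExamRecord(
            patient_id="P", sex="female", age_at_exam=62.0, region="chest",
            dlp=300.0, organ_doses={o: v * 300 for o, v in template.unit_organ_doses.items()},
        )
        scaled = ck.ExamRecord(
            patient_id="P", sex="female", age_at_exam=62.0, region="chest",
            dlp=300.0 * scale,
            organ_doses={o: d * scale for o, d in base.organ_doses.items()},
        )
        m0 = ck.compute_metrics(base, tables)
        m1 = ck.compute_metrics(scaled, tables)
        for name in ("e_dlp", "e_od", "ri", "ri_rp", "e_r"):
            assert getattr(m1, name) == pytest.approx(
                scale * getattr(m0, name), rel=1e-9
            )
        assert m1.f == pytest.approx(m0.f, rel=1e-9)


class TestAccumulation:
    def test_single_exam_equals_per_exam(self, tables, chest_exam):
        p = ck.accumulate_patient([chest_exam], tables)
        assert p.cumulative == p.per_exam[0]

    def test_two_identical_exams_double_everything(self, tables, chest_exam):
        p = ck.accumulate_patient([chest_exam, chest_exam], tables)
        single = p.per_exam[0]
        for name in ("e_dlp", "e_od", "ri", "ri_rp", "e_r"):
            assert getattr(p.cumulative, name) == pytest.approx(
                2 * getattr(single, name), rel=1e-12
            )
        assert p.cumulative.f == pytest.approx(single.f, rel=1e-12)

    def test_two_ages_canonical_vs_alternative_e_r(self, tables):
        """Hand-checkable two-exam toy: cumulative E_r is the sum of the
        per-exam f*E_OD terms and differs from cum_f * cum_E_OD."""
        # different ages AND different dose-vector shapes, otherwise the
        # proportional-protocol property makes the two definitions coincide
        e1 = make_exam(sex="male", age=40.0, lung=20.0)
        e2 = make_exam(sex="male", age=75.0, stomach=15.0, colon=10.0)
        m1 = ck.compute_metrics(e1, tables)
        m2 = ck.compute_metrics(e2, tables)
        p = ck.accumulate_patient([e1, e2], tables)
        assert p.cumulative.e_r == pytest.approx(m1.e_r + m2.e_r, rel=1e-12)
        cum_f = (m1.ri + m2.ri) / (m1.ri_rp + m2.ri_rp)
        assert p.cumulative.f == pytest.approx(cum_f, rel=1e-12)
        assert p.e_r_from_cumulative_f == pytest.approx(
            cum_f * (m1.e_od + m2.e_od), rel=1e-12
        )
        # ages differ, so f differs between exams and the two E_r's diverge
        assert p.cumulative.e_r != pytest.approx(p.e_r_from_cumulative_f, rel=1e-6)

    def test_mixed_ids_rejected(self, tables):
        a = make_exam(lung=1.0)
        b = ck.ExamRecord(patient_id="OTHER", sex="female", age_at_exam=50.0,
                          region="chest", dlp=1.0, organ_doses={"lung": 1.0})
        with pytest.raises(ConsistencyError):
            ck.accumulate_patient([a, b], tables)

    def test_decreasing_ages_rejected(self, tables):
        a = make_exam(age=60.0, lung=1.0)
        b = make_exam(age=50.0, lung=1.0)
        with pytest.raises(ConsistencyError):
            ck.accumulate_patient([a, b], tables)


class TestFilter:
    def _patient(self, tables, e_od_target):
        # lung-only exam: e_od = 0.12 * dose, so dose = target / 0.12
        exam = make_exam(age=60.0, lung=e_od_target / 0.12)
        return ck.accumulate_patient([exam], tables)

    def test_inclusive_boundary(self, tables):
        below = self._patient(tables, 99.9)
        at = self._patient(tables, 100.0)
        above = self._patient(tables, 150.0)
        kept = ck.filter_cohort([below, at, above], threshold=100.0)
        assert [p.cumulative.e_od for p in kept] == pytest.approx([100.0, 150.0])

    def test_empty_input(self):
        assert ck.filter_cohort([]) == []

    def test_order_preserved(self, tables):
        ps = [self._patient(tables, v) for v in (300.0, 120.0, 80.0, 101.0)]
        kept = ck.filter_cohort(ps)
        assert [p.cumulative.e_od for p in kept] == pytest.approx([300.0, 120.0, 101.0])


class TestFramePath:
    def test_frame_matches_record_path(self, tables, small_cohort_frame):
        """Vectorised engine agrees with the record-level computation."""
        sample = small_cohort_frame.head(40)
        frame = compute_exam_metrics_frame(sample, tables)
        organ_cols = [c for c in tables.organs if c in sample.columns]
        for idx, row in sample.iterrows():
            doses = {o: row[o] for o in organ_cols if pd.notna(row[o])}
            exam = ck.ExamRecord(
                patient_id=str(row.patient_id), sex=row.sex,
                age_at_exam=row.age_at_exam, region=row.region, dlp=row.dlp,
                organ_doses=doses,
            )
            m = ck.compute_metrics(exam, tables)
            for name in ("e_dlp", "e_od", "ri", "ri_rp", "f", "e_r"):
                assert frame.loc[idx, name] == pytest.approx(
                    getattr(m, name), rel=1e-9
                ), name

    def test_accumulation_frame_matches_records(self, tables, small_cohort_frame, small_patient_frame):
        pid = small_patient_frame.patient_id.iloc[0]
        sub = small_cohort_frame[small_cohort_frame.patient_id == pid]
        organ_cols = [c for c in tables.organs if c in sub.columns]
        exams = [
            ck.ExamRecord(
                patient_id=str(r.patient_id), sex=r.sex, age_at_exam=r.age_at_exam,
                region=r.region, dlp=r.dlp,
                organ_doses={o: getattr(r, o) for o in organ_cols if pd.notna(getattr(r, o))},
            )
            for r in sub.itertuples()
        ]
        p = ck.accumulate_patient(exams, tables)
        row = small_patient_frame[small_patient_frame.patient_id == pid].iloc[0]
        for name in ("e_dlp", "e_od", "ri", "ri_rp", "f", "e_r"):
            assert row[name] == pytest.approx(getattr(p.cumulative, name), rel=1e-9)

    def test_negative_dose_names_cell(self, tables, small_cohort_frame):
        bad = small_cohort_frame.head(3).copy()
        bad.loc[bad.index[1], "lung"] = -1.0
        with pytest.raises(ValueError, match="lung"):
            validate_exam_frame(bad, tables)

    def test_unknown_organ_column_rejected(self, tables, small_cohort_frame):
        bad = small_cohort_frame.head(3).copy()
        bad["eyeball"] = 1.0
        with pytest.raises(VocabularyError, match="eyeball"):
            validate_exam_frame(bad, tables)

    def test_sex_incompatible_dose_rejected(self, tables, small_cohort_frame):
        bad = small_cohort_frame.head(3).copy()
        bad["sex"] = "male"
        bad["uterus"] = 5.0
        with pytest.raises(ValueError, match="uterus"):
            validate_exam_frame(bad, tables)


class TestEstimators:
    def test_pipeline_compose(self, tables, small_cohort_frame):
        from sklearn.pipeline import Pipeline

        pipe = Pipeline(
            [
                ("metrics", ck.ExamMetrics(tables=tables)),
                ("patients", ck.PatientAccumulator()),
                ("filter", ck.CohortFilter(threshold=100.0)),
            ]
        )
        out = pipe.fit_transform(small_cohort_frame)
        assert out["e_od"].min() >= 100.0
        assert set(ck.dose_metrics.METRIC_COLUMNS) <= set(out.columns)

    def test_clone_and_params(self):
        from sklearn.base import clone

        filt = ck.CohortFilter(threshold=42.0)
        assert clone(filt).threshold == 42.0
        assert filt.get_params() == {"threshold": 42.0}
        filt.set_params(threshold=7.0)
        assert filt.threshold == 7.0
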