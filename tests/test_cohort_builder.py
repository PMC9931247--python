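import numpy as np
import pandas as pd
import pytest

from obesity_lca.cohort_builder import (
    DROPPED,
    EXCLUSION_NO_PRE_INDEX,
    EXCLUSION_NO_VISITS,
    build_demographics,
    build_temporal_features,
    categorize_age,
    classify_medicaid,
    classify_race,
    identify_index_visits,
)
from obesity_lca.scenarios import recovery_config
from obesity_lca.synthetic_cohort import generate_cases
from tests.conftest import make_cohort, make_visits


class TestIdentifyIndexVisits:
    def test_roles_assigned_around_first_obese_visit(self):
        tables = make_cohort(make_visits("p1", [(0, -100), (1, 0), (1, 90)]))
        out = identify_index_visits(tables)
        roles = out.visits.set_index("visit_id")["visit_role"]
        assert roles["p1-v0"] == "pre"
        assert roles["p1-v1"] == "index"
        assert roles["p1-v2"] == "post"

    def test_first_visit_obese_excluded_without_pre_index(self):
        tables = make_cohort(make_visits("p1", [(1, 0), (1, 90)]))
        out = identify_index_visits(tables)
        assert len(out.patients) == 0
        assert out.exclusions.iloc[0]["reason"] == EXCLUSION_NO_PRE_INDEX

    def test_post_index_visit_not_required(self):
        tables = make_cohort(make_visits("p1", [(0, -100), (1, 0)]))
        out = identify_index_visits(tables)
        assert len(out.patients) == 1
        assert "post" not in set(out.visits["visit_role"])

    def test_patient_with_no_visits_excluded_not_raised(self):
        tables = make_cohort(make_visits("p1", [(0, -10), (1, 0)]))
        extra = pd.DataFrame(
            [{c: v for c, v in zip(tables.patients.columns,
                                   ["p2", "case", "p2", "Male", "White", "", 0, -3000])}]
        )
        tables.patients = pd.concat([tables.patients, extra], ignore_index=True)
        out = identify_index_visits(tables)
        assert set(out.patients["patient_id"]) == {"p1"}
        assert dict(zip(out.exclusions["patient_id"], out.exclusions["reason"]))["p2"] == EXCLUSION_NO_VISITS

    def test_same_day_ties_broken_by_visit_id(self):
        tables = make_cohort(make_visits("p1", [(0, 0), (1, 0), (0, 40)]))
        out = identify_index_visits(tables)
        roles = out.visits.set_index("visit_id")["visit_role"]
        assert roles["p1-v0"] == "pre" and roles["p1-v1"] == "index" and roles["p1-v2"] == "post"

    def test_idempotent_on_own_output(self):
        tables = make_cohort(make_visits("p1", [(0, -100), (1, 0), (1, 90)]))
        once = identify_index_visits(tables)
        twice = identify_index_visits(once)
        pd.testing.assert_frame_equal(once.visits, twice.visits)
        pd.testing.assert_frame_equal(once.patients, twice.patients)

    def test_reproduces_generator_roles_exactly(self):
        config = recovery_config(seed=41, n_cases=300)
        cases, _ = generate_cases(config)
        blinded = make_cohort([])  # rebuild with roles wiped
        blinded.patients = cases.patients
        blinded.visits = cases.visits.assign(visit_role="other")
        blinded.diagnoses = cases.diagnoses
        out = identify_index_visits(blinded)
        lhs = out.visits.sort_values("visit_id")[["visit_id", "visit_role"]]
        rhs = cases.visits.sort_values("visit_id")[["visit_id", "visit_role"]]
        pd.testing.assert_frame_equal(lhs.reset_index(drop=True), rhs.reset_index(drop=True))


class TestBuildTemporalFeatures:
    def test_hand_built_grid(self):
        visits = (
            make_visits("p1", [(0, -100), (1, 0)], roles=["pre", "index"])
            + make_visits("p2", [(0, -50), (1, 0), (0, 60)], roles=["pre", "index", "post"])
            + make_visits("p3", [(0, -10), (1, 0)], roles=["pre", "index"])
        )
        dx = [
            ("p1-v0", "Asthma"),
            ("p2-v1", "Asthma"),
            ("p2-v2", "Eczema"),
            ("p3-v0", "Asthma"),
            ("p3-v1", "Eczema"),
        ]
        fm = build_temporal_features(make_cohort(visits, dx))
        expected = pd.DataFrame(
            [[1, 0, 0, 0], [0, 1, 0, 1], [1, 0, 1, 0]],
            index=pd.Index(["p1", "p2", "p3"], name="patient_id"),
            columns=["1-Asthma", "2-Asthma", "2-Eczema", "3-Eczema"],
        ).astype(np.uint8)
        pd.testing.assert_frame_equal(fm.data, expected)

    def test_empty_diagnoses_gives_zero_matrix_of_right_shape(self):
        visits = make_visits("p1", [(0, -100), (1, 0)], roles=["pre", "index"])
        vocab = ["1-A", "2-B"]
        from obesity_lca.temporal import TemporalDiagnosis

        fm = build_temporal_features(
            make_cohort(visits), [TemporalDiagnosis.parse(v) for v in vocab]
        )
        assert fm.data.shape == (1, 2)
        assert (fm.data.to_numpy() == 0).all()

    def test_unknown_visit_reference_raises(self):
        visits = make_visits("p1", [(0, -100), (1, 0)], roles=["pre", "index"])
        with pytest.raises(ValueError, match="unknown visit"):
            build_temporal_features(make_cohort(visits, [("nope-v9", "Asthma")]))

    def test_other_visit_diagnoses_ignored(self):
        visits = make_visits(
            "p1", [(0, -300), (0, -100), (1, 0)], roles=["other", "pre", "index"]
        )
        fm = build_temporal_features(make_cohort(visits, [("p1-v0", "Asthma")]))
        assert fm.data.shape[1] == 0


@pytest.mark.parametrize(
    "race, ethnicity, expected",
    [
        ("White", "Hispanic or Latino", "Hispanic"),
        (None, None, "Unknown"),
        ("", "", "Unknown"),
        ("Asian", "Not Hispanic or Latino", "Asian"),
        ("Black or African American", "Not Hispanic or Latino", "Black/African American"),
        (None, "Hispanic or Latino", "Hispanic"),
        ("Some Other Race", "Not Hispanic or Latino", "Heterogeneous Other"),
        ("White", None, "White"),
    ],
)
def test_classify_race(race, ethnicity, expected):
    assert classify_race(race, ethnicity) == expected


class TestClassifyMedicaid:
    def _visits(self, index_ins, others=()):
        rows = make_visits(
            "p1",
            [(0, -100), (1, 0)] + [(0, d) for d, _ in others],
            roles=["pre", "index"] + ["other"] * len(others),
            insurance=["", index_ins] + [ins for _, ins in others],
        )
        return pd.DataFrame(rows)

    def test_multi_payer_index_with_medicaid_enrolled(self):
        assert classify_medicaid(self._visits("Commercial|Medicaid")) is True

    def test_commercial_only_index_not_enrolled(self):
        assert classify_medicaid(self._visits("Commercial")) is False

    def test_empty_index_falls_back_to_window(self):
        assert classify_medicaid(self._visits("", [(200, "CHIP")])) is True
        assert classify_medicaid(self._visits("", [(-200, "Commercial")])) is False

    def test_fallback_window_is_bounded(self):
        assert classify_medicaid(self._visits("", [(400, "CHIP")])) == DROPPED
        assert classify_medicaid(self._visits("", [(400, "CHIP")]), window_days=500) is True

    def test_one_sided_window_ignores_lookback(self):
        v = self._visits("", [(-200, "CHIP")])
        assert classify_medicaid(v) is True
        assert classify_medicaid(v, two_sided=False) == DROPPED

    def test_no_insurance_anywhere_dropped(self):
        assert classify_medicaid(self._visits("")) == DROPPED


@pytest.mark.parametrize(
    "age, expected",
    [(2.0, "2-4"), (4.9, "2-4"), (5.0, "5-11"), (11.99, "5-11"), (12.0, "12-18"), (18.9, "12-18")],
)
def test_categorize_age_bins(age, expected):
    assert categorize_age(age) == expected


@pytest.mark.parametrize("age", [1.9, 19.0, -3.0])
def test_categorize_age_out_of_range(age):
    with pytest.raises(ValueError):
        categorize_age(age)


def test_build_demographics_drops_uninsured_and_logs():
    rows = make_visits(
        "p1", [(0, -100), (1, 0)], roles=["pre", "index"], insurance=["", "Medicaid"]
    ) + make_visits("p2", [(0, -100), (1, 0)], roles=["pre", "index"], insurance=["", ""])
    tables = make_cohort(rows)
    demo, out = build_demographics(tables)
    assert set(demo["patient_id"]) == {"p1"}
    assert demo.iloc[0]["medicaid_enrolled"]
    assert "p2" in set(out.exclusions["patient_id"])
    assert set(out.patients["patient_id"]) == {"p1"}
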