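import math

import numpy as np
import pandas as pd
import pytest

from moaclin import (
    ClinicalCohort,
    CohortSchema,
    ObjectiveSpec,
    compute_feature_log_ratios,
    compute_objective_deltas,
    load_cohort,
    validation_report,
    write_cohort,
)
from moaclin.cohort import (
    MDS_UPDRS_III,
    OLFACTORY,
    PANDA,
    CohortValidationError,
)

from conftest import make_long_frame, two_visit_rows

OBJ_SPECS = (
    ObjectiveSpec(PANDA, "higher_is_better"),
    ObjectiveSpec(MDS_UPDRS_III, "lower_is_better"),
    ObjectiveSpec(OLFACTORY, "higher_is_better"),
)


def one_patient_frame():
    return make_long_frame(two_visit_rows("P001", "2FL", {
        MDS_UPDRS_III: (30, 25), PANDA: (20, 22), OLFACTORY: (8, 10),
    }))


class TestLoadCohort:
    def test_minimal_long_table(self, tmp_path):
        path = tmp_path / "cohort.csv"
        one_patient_frame().to_csv(path, index=False)
        cohort = load_cohort(str(path))
        assert cohort.n_patients == 1
        assert set(cohort.objectives) == {MDS_UPDRS_III, PANDA, OLFACTORY}
        assert cohort.parameters == ()
        report = validation_report(cohort)
        assert all(v == {"baseline": 0, "V2": 0}
                   for v in report["missingness"].values())

    def test_duplicate_triple_rejected(self, tmp_path):
        df = pd.concat([one_patient_frame(), one_patient_frame().iloc[[0]]])
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="duplicate"):
            load_cohort(str(path))

    def test_unknown_visit_rejected(self):
        df = one_patient_frame()
        df.loc[0, "visit"] = "V7"
        with pytest.raises(CohortValidationError, match="visit"):
            ClinicalCohort(df, objectives=(MDS_UPDRS_III,), parameters=())

    def test_nan_sentinel_rejected(self):
        df = one_patient_frame()
        df.loc[0, "value"] = np.nan
        with pytest.raises(CohortValidationError, match="finite"):
            ClinicalCohort(df, objectives=(MDS_UPDRS_III,), parameters=())

    def test_synthetic_fixture_counts(self, study_cohort, tmp_path):
        cohort, _ = study_cohort
        path = tmp_path / "study.csv"
        write_cohort(cohort, str(path))
        reloaded = load_cohort(str(path))
        assert reloaded.n_patients == 72
        assert reloaded.arms.value_counts().tolist() == [24, 24, 24]

    def test_roundtrip_preserves_table(self, tmp_path):
        df = make_long_frame(
            two_visit_rows("P001", "2FL", {MDS_UPDRS_III: (30, 25), "Tfh": (4.0, 8.0)})
            + two_visit_rows("P002", "PA+BA", {MDS_UPDRS_III: (41, 44), "Tfh": (5.0, 5.0)})
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(p1, index=False)
        c1 = load_cohort(str(p1))
        write_cohort(c1, str(p2))
        c2 = load_cohort(str(p2))
        key = ["patient_id", "visit", "variable"]
        left = c1.data.sort_values(key).reset_index(drop=True)
        right = c2.data.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)

    def test_wide_layout_equals_long(self, tmp_path):
        wide = pd.DataFrame({
            "patient_id": ["P001"], "arm": ["2FL"],
            f"{MDS_UPDRS_III}_baseline": [30], f"{MDS_UPDRS_III}_V2": [25],
            "Tfh_baseline": [4.0], "Tfh_V2": [8.0],
        })
        pw, pl = tmp_path / "wide.csv", tmp_path / "long.csv"
        wide.to_csv(pw, index=False)
        make_long_frame(two_visit_rows("P001", "2FL", {
            MDS_UPDRS_III: (30, 25), "Tfh": (4.0, 8.0),
        })).to_csv(pl, index=False)
        cw, cl = load_cohort(str(pw)), load_cohort(str(pl))
        key = ["patient_id", "visit", "variable"]
        pd.testing.assert_frame_equal(
            cw.data.sort_values(key).reset_index(drop=True).astype({"value": float}),
            cl.data.sort_values(key).reset_index(drop=True).astype({"value": float}),
        )

    def test_tsv_autodetected(self, tmp_path):
        path = tmp_path / "cohort.tsv"
        one_patient_frame().to_csv(path, sep="\t", index=False)
        assert load_cohort(str(path)).n_patients == 1


class TestObjectiveDeltas:
    def test_improvements_map_to_negative(self):
        cohort = ClinicalCohort(one_patient_frame(),
                                objectives=tuple(s.name for s in OBJ_SPECS),
                                parameters=())
        m = compute_objective_deltas(cohort, OBJ_SPECS)
        row = m.values.loc["P001"]
        assert row[MDS_UPDRS_III] == -5   # 30 -> 25, lower is better
        assert row[PANDA] == -2           # 20 -> 22, higher is better, flipped
        assert row[OLFACTORY] == -2       # 8 -> 10, flipped

    def test_no_change_gives_zero_row(self):
        df = make_long_frame(two_visit_rows("P001", "2FL", {
            MDS_UPDRS_III: (30, 30), PANDA: (20, 20), OLFACTORY: (8, 8),
        }))
        cohort = ClinicalCohort(df, tuple(s.name for s in OBJ_SPECS), ())
        m = compute_objective_deltas(cohort, OBJ_SPECS)
        assert (m.values.loc["P001"] == 0).all()

    def test_incomplete_patient_excluded_with_reason(self):
        df = make_long_frame(
            two_visit_rows("P001", "2FL", {
                MDS_UPDRS_III: (30, 25), PANDA: (20, 22), OLFACTORY: (8, 10),
            })
            + two_visit_rows("P002", "2FL", {
                MDS_UPDRS_III: (30, 25), PANDA: (20, 22),
            })
            + [("P002", "2FL", "baseline", OLFACTORY, 8)]  # no V2
        )
        cohort = ClinicalCohort(df, tuple(s.name for s in OBJ_SPECS), ())
        m = compute_objective_deltas(cohort, OBJ_SPECS)
        assert list(m.values.index) == ["P001"]
        assert "P002" in m.excluded
        assert OLFACTORY in m.excluded["P002"] and "V2" in m.excluded["P002"]
        assert m.n_rows + len(m.excluded) == cohort.n_patients

    def test_absent_objective_raises(self):
        cohort = ClinicalCohort(one_patient_frame(),
                                objectives=(MDS_UPDRS_III,), parameters=())
        with pytest.raises(KeyError, match="absent"):
            compute_objective_deltas(cohort, (ObjectiveSpec("grip strength",
                                                            "higher_is_better"),))

    def test_sign_flip_negates_column(self, study_cohort):
        cohort, _ = study_cohort
        flipped = tuple(
            ObjectiveSpec(s.name, "lower_is_better"
                          if s.direction == "higher_is_better" else "higher_is_better")
            for s in OBJ_SPECS
        )
        a = compute_objective_deltas(cohort, OBJ_SPECS).values
        b = compute_objective_deltas(cohort, flipped).values
        pd.testing.assert_frame_equal(a, -b)


class TestFeatureLogRatios:
    def _cohort(self, params):
        rows = two_visit_rows("P001", "2FL", {MDS_UPDRS_III: (30, 25)})
        for i, (pid_vals) in enumerate(params):
            for pid, (b, v2) in pid_vals.items():
                rows += two_visit_rows(pid, "2FL", {f"param{i}": (b, v2)})
        df = make_long_frame(rows)
        return ClinicalCohort(df, objectives=(MDS_UPDRS_III,),
                              parameters=tuple(f"param{i}" for i in range(len(params))))

    def test_doubling_gives_ln2(self):
        cohort = self._cohort([{"P001": (4.0, 8.0)}])
        m = compute_feature_log_ratios(cohort)
        assert m.values.loc["P001", "param0"] == pytest.approx(math.log(2), abs=1e-12)

    def test_equal_visits_give_zero(self):
        cohort = self._cohort([{"P001": (5.0, 5.0)}])
        m = compute_feature_log_ratios(cohort)
        assert m.values.loc["P001", "param0"] == 0.0

    def test_half_min_pseudocount(self):
        # column's smallest positive value is 0.5 -> zero replaced by 0.25
        cohort = self._cohort([{"P001": (0.0, 2.0), "P002": (0.5, 1.0)}])
        m = compute_feature_log_ratios(cohort, "half_min")
        assert m.values.loc["P001", "param0"] == pytest.approx(math.log(2.0 / 0.25),
                                                               abs=1e-9)
        assert m.values.loc["P001", "param0"] == pytest.approx(2.0794, abs=5e-5)
        (event,) = m.policy_applications
        assert event["patient_id"] == "P001" and event["replacement"] == 0.25

    def test_exclude_cell_policy(self):
        cohort = self._cohort([{"P001": (0.0, 2.0), "P002": (0.5, 1.0)}])
        m = compute_feature_log_ratios(cohort, "exclude_cell")
        assert math.isnan(m.values.loc["P001", "param0"])
        assert m.values.loc["P002", "param0"] == pytest.approx(math.log(2.0))

    def test_mostly_nonpositive_parameter_warns(self):
        cohort = self._cohort([{"P001": (0.0, 2.0), "P002": (-1.0, 1.0),
                                "P003": (3.0, 4.0)}])
        with pytest.warns(UserWarning, match="param0"):
            compute_feature_log_ratios(cohort)

    def test_antisymmetric_under_visit_swap(self, study_cohort):
        cohort, _ = study_cohort
        swapped_df = cohort.data.copy()
        swapped_df["visit"] = swapped_df["visit"].map(
            {"baseline": "V2", "V2": "baseline"}
        )
        swapped = ClinicalCohort(swapped_df, cohort.objectives, cohort.parameters)
        a = compute_feature_log_ratios(cohort).values
        b = compute_feature_log_ratios(swapped).values
        pd.testing.assert_frame_equal(a, -b)

    def test_schema_override_objective_set(self, tmp_path):
        df = make_long_frame(two_visit_rows("P001", "2FL", {
            "custom score": (10, 12), "Tfh": (4.0, 8.0),
        }))
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        cohort = load_cohort(str(path), CohortSchema(objectives=("custom score",)))
        assert cohort.objectives == ("custom score",)
        assert cohort.parameters == ("Tfh",)
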