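import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from careflow import (
    DegenerateInputError,
    StateModelSpec,
    build_event_log,
    classify_temperature,
    collapse_consecutive,
    infection_activity,
    infection_flag,
    organ_activity,
)
from careflow.errors import SpecificationError
from careflow.states import INFECTION_LABELS, ORGAN_LABELS, classify_patient

from conftest import make_patient


class TestClassifyTemperature:
    @pytest.mark.parametrize("temp,expected", [
        (35.2, "Low Temperature"),
        (38.4, "High Temperature"),
        (36.0, "Normal Temperature"),   # closed lower boundary
        (37.5, "Normal Temperature"),   # closed upper boundary
        (36.8, "Normal Temperature"),
    ])
    def test_three_way_partition(self, temp, expected):
        assert classify_temperature(temp) == expected

    def test_threshold_sharpness(self):
        eps = 1e-9
        assert classify_temperature(36.0 - eps) == "Low Temperature"
        assert classify_temperature(37.5 + eps) == "High Temperature"


class TestInfectionFlag:
    @pytest.mark.parametrize("wbc,expected", [
        (13.2, True),   # leukocytosis
        (3.1, True),    # leukopenia
        (8.0, False),
        (12.0, False),  # strict inequality at both thresholds
        (4.0, False),
    ])
    def test_flag(self, wbc, expected):
        assert infection_flag(wbc) is expected


class TestInfectionActivity:
    def test_combined_state(self):
        assert infection_activity("High Temperature", True, False) == \
            "Infection + High Temperature"

    def test_plain_temperature_state(self):
        assert infection_activity("Normal Temperature", False, False) == \
            "Normal Temperature"

    def test_sepsis_takes_precedence(self):
        assert infection_activity("Low Temperature", False, True) == "Sepsis"
        assert infection_activity("High Temperature", True, True) == "Sepsis"

    def test_label_universe_has_seven_activities(self):
        labels = {
            infection_activity(t, i, s)
            for t in ("Low Temperature", "Normal Temperature", "High Temperature")
            for i in (False, True) for s in (False, True)
        }
        assert labels == set(INFECTION_LABELS)
        assert len(INFECTION_LABELS) == 7


class TestOrganActivity:
    @pytest.mark.parametrize("trp,crt,ast,expected", [
        (0.06, 1.0, 20, "Cardiac Damage"),
        (0.01, 2.0, 20, "Renal Damage"),
        (0.01, 1.0, 55, "Liver Damage"),
        (0.06, 2.0, 55, "Multiorgan Damage"),
        (0.01, 1.0, 20, "Low Risk"),
        (0.06, 2.0, 20, "Renal + Cardiac Damage"),
        (0.06, 1.0, 55, "Liver + Cardiac Damage"),
        (0.01, 2.0, 55, "Renal + Liver Damage"),
    ])
    def test_flag_aggregation(self, trp, crt, ast, expected):
        assert organ_activity(trp, crt, ast, False) == expected

    def test_sepsis_overrides_all_flags(self):
        assert organ_activity(0.06, 2.0, 55, True) == "Sepsis"

    def test_label_universe_has_nine_activities(self):
        labels = {organ_activity(t, c, a, False)
                  for t in (0.01, 0.06) for c in (1.0, 2.0) for a in (20, 55)}
        labels.add("Sepsis")
        assert labels == set(ORGAN_LABELS)
        assert len(ORGAN_LABELS) == 9


class TestCollapseConsecutive:
    @pytest.mark.parametrize("seq,expected", [
        (["A", "A", "B", "B", "A"], ["A", "B", "A"]),
        (["A"], ["A"]),
        ([], []),
        (["A", "B", "C"], ["A", "B", "C"]),
    ])
    def test_examples(self, seq, expected):
        assert collapse_consecutive(seq) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.sampled_from("ABCD"), max_size=30))
    def test_matches_groupby_oracle(self, seq):
        oracle = [k for k, _ in itertools.groupby(seq)]
        out = collapse_consecutive(seq)
        assert out == oracle
        # output is a subsequence with no adjacent repeats
        assert all(x != y for x, y in zip(out, out[1:]))


class TestClassifyPatient:
    def test_worked_hourly_example(self):
        """Hand-simulated hourly classification and collapse."""
        tab = make_patient("p1", temp=[36.5, 38.0, 38.1, 36.9],
                           wbc=[8, 8, 13, 13])
        seq = classify_patient(tab, StateModelSpec("infection"))
        assert [label for _, label in seq.states] == [
            "Normal Temperature", "High Temperature",
            "Infection + High Temperature", "Infection + Normal Temperature",
        ]
        assert [h for h, _ in seq.states] == [1, 2, 3, 4]

    def test_constant_values_collapse_to_single_event(self):
        tab = make_patient("p1", temp=[37.0] * 6, wbc=[8] * 6)
        seq = classify_patient(tab, StateModelSpec("infection"))
        assert [label for _, label in seq.states] == ["Normal Temperature"]

    def test_locf_carries_sparse_labs_forward(self):
        tab = make_patient("p1", temp=[37.0, 38.0, 38.0, 38.0],
                           wbc=[13, np.nan, np.nan, np.nan])
        seq = classify_patient(tab, StateModelSpec("infection"))
        assert [label for _, label in seq.states] == [
            "Infection + Normal Temperature", "Infection + High Temperature"]

    def test_hours_before_first_observation_emit_nothing(self):
        tab = make_patient("p1", temp=[37.0, 37.0, 37.0],
                           wbc=[np.nan, np.nan, 8.0])
        seq = classify_patient(tab, StateModelSpec("infection"))
        assert seq.states == [(3, "Normal Temperature")]

    def test_sepsis_label_terminates_trace(self):
        tab = make_patient("p1", temp=[37.0, 37.0, 39.0, 39.0],
                           wbc=[8, 8, 8, 8], sepsis=[0, 0, 1, 1])
        seq = classify_patient(tab, StateModelSpec("infection"))
        assert [label for _, label in seq.states] == \
            ["Normal Temperature", "Sepsis"]
        assert seq.states[-1][0] == 3

    def test_artifact_temperature_treated_as_missing(self):
        tab = make_patient("p1", temp=[37.0, 46.0, 38.0], wbc=[8, 8, 8])
        seq = classify_patient(tab, StateModelSpec("infection"))
        # hour 2's 46 °C is an artifact: LOCF keeps Normal until the 38.0
        assert [label for _, label in seq.states] == \
            ["Normal Temperature", "High Temperature"]


class TestBuildEventLog:
    def test_patient_without_required_variable_is_excluded(self):
        with_wbc = make_patient("p1", temp=[37.0, 37.0], wbc=[8, 8])
        without = make_patient("p2", temp=[37.0, 37.0])
        log, report = build_event_log([with_wbc, without],
                                      StateModelSpec("infection"))
        assert log.case_ids == ["p1"]
        assert report["patients_excluded_missing_variables"] == 1
        assert report["excluded_ids"] == ["p2"]

    def test_empty_cohort_after_filtering_raises_with_report(self):
        tab = make_patient("p1", temp=[37.0, 37.0])  # no WBC at all
        with pytest.raises(DegenerateInputError, match="stage report"):
            build_event_log([tab], StateModelSpec("infection"))

    def test_stage_report_counts_reconcile(self, small_cohort):
        _, cohort = small_cohort
        log, report = build_event_log(cohort, StateModelSpec("infection"))
        assert report["patients_in"] == len(cohort)
        assert report["patients_kept"] + report["patients_excluded_missing_variables"] \
            == report["patients_in"]
        assert report["n_unique_traces"] <= report["patients_kept"] == len(log)
        assert report["n_events"] == sum(len(t) for t in log.traces)

    def test_label_universe_closure(self, small_cohort):
        _, cohort = small_cohort
        log, _ = build_event_log(cohort, StateModelSpec("infection"))
        assert log.activity_universe <= set(INFECTION_LABELS)

    def test_sepsis_only_final_in_absorbing_traces(self, small_cohort):
        _, cohort = small_cohort
        log, _ = build_event_log(cohort, StateModelSpec("infection"))
        for t in log.traces:
            if "Sepsis" in t.activities:
                assert t.activities[-1] == "Sepsis"
                assert t.activities.count("Sepsis") == 1


class TestStateModelSpec:
    def test_inverted_thresholds_rejected(self):
        with pytest.raises(SpecificationError):
            StateModelSpec("infection", thresholds={
                "temp_low": 38.0, "temp_high": 37.5, "wbc_high": 12.0,
                "wbc_low": 4.0, "troponin": 0.04, "creatinine": 1.3, "ast": 40.0})

    def test_unknown_model_rejected(self):
        with pytest.raises(SpecificationError):
            StateModelSpec("kidney")

    def test_default_required_variables(self):
        assert StateModelSpec("infection").required_variables == ["Temp", "WBC"]
        assert StateModelSpec("organ").required_variables == \
            ["Creatinine", "TroponinI", "AST"]

    def test_from_yaml_config(self, tmp_path):
        path = tmp_path / "model.yaml"
        path.write_text(
            "model_id: organ\nthresholds:\n  ast: 50.0\nsepsis_absorbing: false\n")
        spec = StateModelSpec.from_config(path)
        assert spec.model_id == "organ"
        assert spec.thresholds["ast"] == 50.0
        assert spec.thresholds["troponin"] == 0.04  # defaults preserved
        assert spec.sepsis_absorbing is False
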