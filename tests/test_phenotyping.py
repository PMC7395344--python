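"""Code detection, adjudication, status assembly and index dates."""

from datetime import date

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ehrpheno.phenotyping import (
    DEFAULT_CODE_MAP,
    STATUS_CASE,
    STATUS_CONTROL,
    STATUS_INELIGIBLE,
    STATUS_REJECTED,
    Occurrence,
    PhenotypeRecord,
    StudyWindow,
    adjudicate_labels,
    assemble_phenotype,
    assign_index_date,
    build_phenotypes,
    detect_code_occurrences,
)

WINDOW = StudyWindow(date(2016, 1, 1), date(2018, 1, 1))


def diag(pid, system, code, d):
    return pd.DataFrame(
        [{"patient_id": pid, "code_system": system, "code": code, "date": d}]
    )


def occ(pid="p1", condition="frailty", source="text", d="2016-05-01", label="positive"):
    return Occurrence(pid, condition, source, date.fromisoformat(d), label)


class TestDetectCodeOccurrences:
    @pytest.mark.parametrize(
        "system,code,condition",
        [
            ("ICD10", "M62.84", "sarcopenia"),
            ("ICD10", "R64", "cachexia"),
            ("ICD10", "R54", "frailty"),
            ("ICD9", "797", "frailty"),
            ("ICD9", "799.4", "cachexia"),
        ],
    )
    def test_phenotype_codes_map(self, system, code, condition):
        out = detect_code_occurrences(diag("p1", system, code, "2016-05-01"), window=WINDOW)
        assert len(out) == 1
        assert out[0].condition == condition
        assert out[0].source == "code" and out[0].label == "positive"

    def test_non_phenotype_code_ignored(self):
        assert detect_code_occurrences(diag("p1", "ICD10", "E11.9", "2016-05-01"), window=WINDOW) == []

    def test_exact_match_no_prefix_by_default(self):
        assert detect_code_occurrences(diag("p1", "ICD9", "797.0", "2016-05-01"), window=WINDOW) == []
        out = detect_code_occurrences(
            diag("p1", "ICD9", "797.0", "2016-05-01"), window=WINDOW, prefix_mode=True
        )
        assert len(out) == 1 and out[0].condition == "frailty"

    def test_out_of_window_filtered(self):
        assert detect_code_occurrences(diag("p1", "ICD10", "R64", "2015-12-31"), window=WINDOW) == []

    def test_without_window_everything_recorded(self):
        out = detect_code_occurrences(diag("p1", "ICD10", "R64", "2015-12-31"))
        assert len(out) == 1

    def test_malformed_date_skipped(self, caplog):
        out = detect_code_occurrences(diag("p1", "ICD10", "R64", "not-a-date"), window=WINDOW)
        assert out == []

    def test_normalization_trims_and_uppercases(self):
        out = detect_code_occurrences(diag("p1", "ICD10", " m62.84 ", "2016-05-01"), window=WINDOW)
        assert len(out) == 1 and out[0].condition == "sarcopenia"


class TestAdjudication:
    # the full 3x3 ordered truth table of the dual-reviewer rule
    TABLE = {
        ("positive", "positive"): "positive",
        ("positive", "uncertain"): "positive",
        ("uncertain", "positive"): "positive",
        ("negative", "negative"): "negative",
        ("negative", "uncertain"): "negative",
        ("uncertain", "negative"): "negative",
        ("uncertain", "uncertain"): "uncertain",
        ("positive", "negative"): "uncertain",
        ("negative", "positive"): "uncertain",
    }

    @pytest.mark.parametrize("pair,expected", sorted(TABLE.items()))
    def test_truth_table(self, pair, expected):
        assert adjudicate_labels(*pair) == expected

    @given(
        st.sampled_from(["positive", "negative", "uncertain"]),
        st.sampled_from(["positive", "negative", "uncertain"]),
    )
    def test_commutative(self, a, b):
        assert adjudicate_labels(a, b) == adjudicate_labels(b, a)

    @given(st.sampled_from(["positive", "negative", "uncertain"]))
    def test_idempotent_on_agreement(self, a):
        assert adjudicate_labels(a, a) == a

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            adjudicate_labels("positive", "maybe")


class TestAssemblePhenotype:
    def test_single_positive_text_occurrence_is_a_text_only_case(self):
        rec = assemble_phenotype("p1", [occ()], True, 70, WINDOW)
        assert rec.status == STATUS_CASE
        assert rec.conditions == frozenset({"frailty"})
        assert rec.detection_source == "text_only"

    def test_only_negative_occurrence_is_rejected_presumptive(self):
        rec = assemble_phenotype("p1", [occ(condition="cachexia", label="negative")], True, 70, WINDOW)
        assert rec.status == STATUS_REJECTED

    def test_uncertain_occurrences_do_not_confirm_a_case(self):
        rec = assemble_phenotype("p1", [occ(label="uncertain")], True, 70, WINDOW)
        assert rec.status == STATUS_REJECTED

    def test_zero_occurrences_adult_with_encounter_is_control_eligible(self):
        rec = assemble_phenotype("p1", [], True, 70, WINDOW)
        assert rec.status == STATUS_CONTROL and rec.conditions == frozenset()

    def test_minor_or_no_encounter_is_ineligible(self):
        assert assemble_phenotype("p1", [], True, 17, WINDOW).status == STATUS_INELIGIBLE
        assert assemble_phenotype("p1", [], False, 70, WINDOW).status == STATUS_INELIGIBLE

    def test_code_and_text_detection_source(self):
        rec = assemble_phenotype("p1", [occ(), occ(source="code")], True, 70, WINDOW)
        assert rec.detection_source == "code_and_text"

    def test_code_only_detection_source(self):
        rec = assemble_phenotype("p1", [occ(source="code")], True, 70, WINDOW)
        assert rec.detection_source == "code_only"

    def test_out_of_window_positive_does_not_confirm(self):
        rec = assemble_phenotype("p1", [occ(d="2015-06-01")], True, 70, WINDOW)
        assert rec.status == STATUS_CONTROL

    def test_foreign_occurrence_rejected(self):
        with pytest.raises(ValueError):
            assemble_phenotype("p2", [occ()], True, 70, WINDOW)


class TestAssignIndexDate:
    def test_case_earliest_positive(self):
        rec = PhenotypeRecord("p1", STATUS_CASE, frozenset({"frailty"}), "text_only")
        occs = [occ(d="2017-01-01"), occ(d="2016-03-04"), occ(d="2016-02-01", label="negative")]
        assert assign_index_date(rec, occs, [], WINDOW) == date(2016, 3, 4)

    def test_control_earliest_encounter(self):
        rec = PhenotypeRecord("p1", STATUS_CONTROL, frozenset(), None)
        dates = [date(2017, 6, 1), date(2016, 2, 2)]
        assert assign_index_date(rec, [], dates, WINDOW) == date(2016, 2, 2)

    def test_control_without_encounter_errors(self):
        rec = PhenotypeRecord("p1", STATUS_CONTROL, frozenset(), None)
        with pytest.raises(ValueError):
            assign_index_date(rec, [], [], WINDOW)

    def test_case_with_only_pre_window_positive_errors(self):
        rec = PhenotypeRecord("p1", STATUS_CASE, frozenset({"frailty"}), "text_only")
        with pytest.raises(ValueError):
            assign_index_date(rec, [occ(d="2015-01-01")], [], WINDOW)


class TestEndToEnd:
    def test_pipeline_recovers_planted_truth_exactly(self, small_cohort):
        """With misspelling within lexicon reach and unambiguous templates the
        computable phenotype has sensitivity = specificity = 1 against the
        planted truth, and index dates match."""
        _, dataset, truth = small_cohort
        phenotypes, _, _ = build_phenotypes(dataset)
        by_pid = phenotypes.set_index("patient_id")
        status_map = {
            "case": STATUS_CASE,
            "rejected_presumptive": STATUS_REJECTED,
            "control": STATUS_CONTROL,
        }
        for pid, planted in truth.patients.items():
            got = by_pid.loc[pid]
            assert got["status"] == status_map[planted["status"]]
            if planted["status"] == "case":
                assert got["conditions"] == ";".join(planted["conditions"])
                assert got["index_date"] == planted["index_date"]

    def test_partition_of_eligible_patients(self, small_cohort):
        _, dataset, _ = small_cohort
        phenotypes, _, _ = build_phenotypes(dataset)
        assert set(phenotypes["status"]) <= {
            STATUS_CASE, STATUS_REJECTED, STATUS_CONTROL, STATUS_INELIGIBLE,
        }
        assert len(phenotypes) == len(dataset.patients)

    def test_code_only_absent_on_generator_defaults(self, small_cohort):
        # codes are planted only alongside text, so code_only never occurs
        _, dataset, _ = small_cohort
        phenotypes, _, _ = build_phenotypes(dataset)
        assert (phenotypes["detection_source"] == "code_only").sum() == 0
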