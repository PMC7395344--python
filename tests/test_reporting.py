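"""Cross-tabulation, report tables and the CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest

from ehrpheno.reporting import (
    case_control_table,
    coded_vs_text_table,
    cross_tab_terms_codes,
    phenotype_summary,
    subgroup_tables,
)


def load_csv(outdir, name):
    kw = {"dtype": {"patient_id": str, "case_id": str, "control_id": str}}
    if name == "phenotypes.csv":
        kw["keep_default_na"] = False
    return pd.read_csv(outdir / name, **kw)


def items(text=(), code=()):
    return (frozenset(text), frozenset(code))


class TestCrossTab:
    def test_single_text_frailty_case(self):
        ct = cross_tab_terms_codes([items(text=["frailty"])])
        assert ct.matrix.loc["text_frailty", "text_frailty"] == 1
        assert ct.matrix.to_numpy().sum() == 1

    def test_hand_enumerated_subsets(self):
        cases = [
            items(text=["sarcopenia", "cachexia"]),
            items(text=["cachexia"]),
            items(text=["sarcopenia", "cachexia", "frailty"]),
        ]
        ct = cross_tab_terms_codes(cases)
        d = ct.derived
        assert d["n_multi_condition"] == 2
        assert d["multi_condition_subsets"]["all_three"] == 1
        assert d["multi_condition_subsets"]["sarcopenia+cachexia"] == 1

    def test_inclusion_exclusion_identity_on_random_sets(self):
        rng = np.random.default_rng(0)
        conditions = ["sarcopenia", "cachexia", "frailty"]
        for _ in range(30):
            cases = []
            for _ in range(int(rng.integers(1, 40))):
                text = [c for c in conditions if rng.random() < 0.5]
                code = [c for c in conditions if rng.random() < 0.3]
                if not text and not code:
                    text = ["frailty"]
                cases.append(items(text, code))
            ct = cross_tab_terms_codes(cases)
            assert (
                ct.derived["more_than_one_code_incl_excl"]
                == ct.derived["more_than_one_code_direct"]
            )
            subsets = ct.derived["multi_condition_subsets"]
            assert sum(subsets.values()) == ct.derived["n_multi_condition"]

    def test_off_diagonal_bounded_by_diagonals(self):
        rng = np.random.default_rng(1)
        conditions = ["sarcopenia", "cachexia", "frailty"]
        cases = [
            items(
                [c for c in conditions if rng.random() < 0.5],
                [c for c in conditions if rng.random() < 0.3],
            )
            for _ in range(50)
        ]
        ct = cross_tab_terms_codes(cases)
        m = ct.matrix
        for i, r in enumerate(m.index):
            for c in m.columns[i + 1 :]:
                assert m.loc[r, c] <= min(m.loc[r, r], m.loc[c, c])


class TestPhenotypeSummaryFixture:
    def test_rates_from_constructed_occurrences(self):
        from datetime import date

        from ehrpheno.phenotyping import Occurrence

        # 9 confirmed + 1 rejected; sarcopenia used positively by 2 of 3
        phenotypes = pd.DataFrame(
            [
                {"patient_id": f"p{i}", "status": "confirmed_case",
                 "detection_source": "text_only", "conditions": "frailty", "index_date": "2016-01-01"}
                for i in range(9)
            ]
            + [
                {"patient_id": "p9", "status": "rejected_presumptive",
                 "detection_source": "", "conditions": "", "index_date": ""}
            ]
        )
        occurrences = [
            Occurrence("p0", "sarcopenia", "text", date(2016, 2, 1), "positive"),
            Occurrence("p1", "sarcopenia", "text", date(2016, 2, 1), "positive"),
            Occurrence("p9", "sarcopenia", "text", date(2016, 2, 1), "negative"),
        ]
        s = phenotype_summary(phenotypes, occurrences)
        assert s["n_presumptive"] == 10
        assert s["confirmation_rate_pct"] == 90.0
        assert s["positive_use"]["sarcopenia"]["rate_pct"] == pytest.approx(66.7)


class TestPipelineReports:
    def test_planted_hypertension_or_direction_recovered(self, pipeline_run):
        _, outdir = pipeline_run
        results = json.loads((outdir / "results.json").read_text())
        rows = {r["variable"]: r for r in results["case_control"]["rows"]}
        assert rows["hypertension"]["result"]["estimate"] > 1.0
        assert rows["bmi"]["result"]["p_value"] < 0.05

    def test_matched_demographics_identical_between_arms(self, pipeline_run):
        _, outdir = pipeline_run
        pairs = load_csv(outdir, "pairs.csv")
        patients = load_csv(outdir, "patients.csv")
        demo = patients.set_index("patient_id")
        for col in ("sex", "race", "birth_year"):
            case_counts = demo.loc[pairs["case_id"], col].value_counts().sort_index()
            ctrl_counts = demo.loc[pairs["control_id"], col].value_counts().sort_index()
            assert (case_counts == ctrl_counts).all()

    def test_variable_identical_within_every_pair_is_flagged(self):
        pairs = pd.DataFrame(
            {"pair_id": [0, 1], "case_id": ["c0", "c1"], "control_id": ["k0", "k1"],
             "birth_year": [1940, 1941], "sex": ["female", "male"], "race": ["white", "white"]}
        )
        base = {
            name: False
            for name in (
                "diabetes_with_complication", "diabetes_without_complication", "hypertension",
                "cardiovascular_disease", "peripheral_vascular_disease", "ckd_stages_3_5",
                "ckd_stage_4", "ckd_stage_5", "any_malignancy", "liver_disease", "depression",
                "aids", "neurologic_conditions", "fractures", "osteoporosis", "charlson_gt2",
                "med_glucocorticoids", "med_dronabinol", "med_megestrol",
                "med_caloric_supplement", "med_testosterone",
            )
        }
        rows = []
        for pid in ("c0", "c1", "k0", "k1"):
            rows.append({"patient_id": pid, "index_date": "2016-01-01", **base,
                         "charlson_index": 0, "bmi": 25.0, "weight": 70.0, "albumin": 4.0,
                         "prealbumin": 20.0, "hba1c": 5.5, "hospitalizations": 0})
        variables = pd.DataFrame(rows)
        report = case_control_table(pairs, variables)
        by_var = {r.variable: r for r in report.rows}
        assert "no_discordant_pairs" in by_var["hypertension"].result.flags

    def test_subgroups_partition_the_cases(self, pipeline_run):
        _, outdir = pipeline_run
        phenotypes = load_csv(outdir, "phenotypes.csv")
        cases = phenotypes[phenotypes["status"] == "confirmed_case"]
        singles = sum((cases["conditions"] == c).sum() for c in ("sarcopenia", "cachexia", "frailty"))
        multi = (cases["conditions"].str.contains(";")).sum()
        assert singles + multi == len(cases)

    def test_multi_condition_case_in_no_subgroup(self, pipeline_run):
        config, outdir = pipeline_run
        phenotypes = load_csv(outdir, "phenotypes.csv")
        pairs = load_csv(outdir, "pairs.csv")
        variables = load_csv(outdir, "variables.csv")
        reports = subgroup_tables(phenotypes, pairs, variables)
        n_sub = sum(r.header.get("n_pairs", 0) for r in reports.values())
        cases = phenotypes[phenotypes["status"] == "confirmed_case"]
        multi_ids = set(cases.loc[cases["conditions"].str.contains(";"), "patient_id"])
        matched_multi = pairs["case_id"].isin(multi_ids).sum()
        assert n_sub == len(pairs) - matched_multi

    def test_coded_vs_text_requires_both_strata(self):
        phenotypes = pd.DataFrame(
            [{"patient_id": "p0", "status": "confirmed_case", "conditions": "frailty",
              "detection_source": "text_only", "index_date": "2016-01-01"}]
        )
        with pytest.raises(ValueError, match="ICD codes"):
            coded_vs_text_table(phenotypes, pd.DataFrame({"patient_id": []}))


class TestCli:
    def test_run_all_writes_all_artifacts(self, tmp_path):
        from typer.testing import CliRunner

        from ehrpheno.cli import app

        config = {"generator": {"n_patients": 300, "rng_seed": 5}}
        cfg_path = tmp_path / "config.json"
        cfg_path.write_text(json.dumps(config))
        outdir = tmp_path / "out"
        runner = CliRunner()
        result = runner.invoke(
            app, ["run-all", "--config", str(cfg_path), "--outdir", str(outdir), "--seed", "5"]
        )
        assert result.exit_code == 0, result.output
        for name in (
            "patients.csv", "notes.jsonl", "mentions.csv", "phenotypes.csv",
            "pairs.csv", "variables.csv", "results.json", "table_case_control.tsv",
            "lexicon.json", "truth.json",
        ):
            assert (outdir / name).exists(), name
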