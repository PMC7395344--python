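"""End-to-end pipeline: simulate -> detect -> match -> analyze -> report.

Each stage reads and writes plain-text artifacts in one output directory, so
every reported number is traceable to an intermediate file.  With a fixed
config and seed the whole run is byte-identical.
"""

from __future__ import annotations

import json
import logging
from datetime import date
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from .clinical_vars import build_variables
from .matching import MatchKey, match_controls, verify_matching
from .nlp_engine import build_lexicon
from .phenotyping import (
    STATUS_CASE,
    STATUS_CONTROL,
    StudyWindow,
    build_phenotypes,
)
from .reporting import (
    case_control_table,
    case_items_from_occurrences,
    coded_vs_text_table,
    cross_tab_terms_codes,
    phenotype_summary,
    subgroup_tables,
    write_report,
)
from .synthetic_ehr import EHRDataset, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Configuration for a full run; every field has a documented default."""

    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    lexicon_edit_distance: int = 1
    matching_seed: int | None = None  # defaults to the generator seed

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls.model_validate(payload)

    def window(self) -> StudyWindow:
        return StudyWindow(self.generator.study_start, self.generator.study_end)


def run_simulate(config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_cohort(config.generator)
    dataset.write(outdir)
    truth.write(outdir / "truth.json")
    logger.info(
        "simulate: %d patients, %d notes, %d diagnoses",
        len(dataset.patients), len(dataset.notes), len(dataset.diagnoses),
    )


def run_detect(config: PipelineConfig, outdir: Path) -> None:
    dataset = EHRDataset.read(outdir)
    lexicon = build_lexicon(max_edit_distance=config.lexicon_edit_distance)
    lexicon.to_json(outdir / "lexicon.json")
    phenotypes, mentions, occurrences = build_phenotypes(dataset, lexicon, config.window())
    mentions.to_csv(outdir / "mentions.csv", index=False)
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    occ = pd.DataFrame(
        [
            {
                "patient_id": o.patient_id,
                "condition": o.condition,
                "source": o.source,
                "date": o.date.isoformat(),
                "label": o.label,
            }
            for o in occurrences
        ],
        columns=["patient_id", "condition", "source", "date", "label"],
    )
    occ.sort_values(["patient_id", "date", "condition", "source"], kind="stable", ignore_index=True, inplace=True)
    occ.to_csv(outdir / "occurrences.csv", index=False)
    logger.info("detect: %d mentions, %d occurrences", len(mentions), len(occ))


def run_match(config: PipelineConfig, outdir: Path) -> None:
    phenotypes = pd.read_csv(outdir / "phenotypes.csv", dtype={"patient_id": str}, keep_default_na=False)
    patients = pd.read_csv(outdir / "patients.csv", dtype={"patient_id": str})
    keys = {
        str(r.patient_id): MatchKey(int(r.birth_year), str(r.sex), str(r.race))
        for r in patients.itertuples(index=False)
    }
    cases = [
        (pid, keys[pid]) for pid in phenotypes.loc[phenotypes["status"] == STATUS_CASE, "patient_id"]
    ]
    pool = [
        (pid, keys[pid]) for pid in phenotypes.loc[phenotypes["status"] == STATUS_CONTROL, "patient_id"]
    ]
    seed = config.matching_seed if config.matching_seed is not None else config.generator.rng_seed
    result = match_controls(cases, pool, rng_seed=seed)
    audit = verify_matching(result, cases, pool)
    if not audit.ok:
        raise AssertionError(f"matching audit failed: {audit.violations}")
    pairs, unmatched = result.to_frames()
    pairs.to_csv(outdir / "pairs.csv", index=False)
    unmatched.to_csv(outdir / "unmatched.csv", index=False)
    logger.info("match: %d pairs, %d unmatched cases", len(pairs), len(unmatched))


def run_analyze(config: PipelineConfig, outdir: Path) -> None:
    dataset = EHRDataset.read(outdir)
    phenotypes = pd.read_csv(outdir / "phenotypes.csv", dtype={"patient_id": str}, keep_default_na=False)
    variables = build_variables(dataset, phenotypes, config.window())
    variables.to_csv(outdir / "variables.csv", index=False)
    logger.info("analyze: %d variable rows", len(variables))


def run_report(config: PipelineConfig, outdir: Path) -> None:
    from .phenotyping import Occurrence

    phenotypes = pd.read_csv(outdir / "phenotypes.csv", dtype={"patient_id": str}, keep_default_na=False)
    patients = pd.read_csv(outdir / "patients.csv", dtype={"patient_id": str})
    pairs = pd.read_csv(outdir / "pairs.csv", dtype={"case_id": str, "control_id": str})
    variables = pd.read_csv(outdir / "variables.csv", dtype={"patient_id": str})
    occ_df = pd.read_csv(outdir / "occurrences.csv", dtype={"patient_id": str})
    occurrences = [
        Occurrence(
            patient_id=str(r.patient_id),
            condition=r.condition,
            source=r.source,
            date=date.fromisoformat(str(r.date)),
            label=r.label,
        )
        for r in occ_df.itertuples(index=False)
    ]
    year = config.generator.study_start.year

    summary = phenotype_summary(phenotypes, occurrences)
    crosstab = cross_tab_terms_codes(case_items_from_occurrences(phenotypes, occurrences))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "table_crosstab.json").write_text(json.dumps(crosstab.to_json(), indent=1, sort_keys=True))
    crosstab.matrix.to_csv(outdir / "table_crosstab.tsv", sep="\t")

    main = case_control_table(pairs, variables, title="case_control", window_start_year=year)
    write_report(main, "table_case_control", outdir)
    coded = coded_vs_text_table(
        phenotypes, variables, title="coded_vs_text", window_start_year=year, patients=patients
    )
    write_report(coded, "table_coded_vs_text", outdir)
    for condition, report in subgroup_tables(phenotypes, pairs, variables, window_start_year=year).items():
        write_report(report, f"table_subgroup_{condition}", outdir)
    results = {
        "summary": summary,
        "crosstab": crosstab.to_json(),
        "case_control": main.to_json(),
        "coded_vs_text": coded.to_json(),
    }
    (outdir / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    logger.info("report: wrote tables for %d pairs", len(pairs))


def run_all(config: PipelineConfig, outdir: str | Path) -> None:
    outdir = Path(outdir)
    run_simulate(config, outdir)
    run_detect(config, outdir)
    run_match(config, outdir)
    run_analyze(config, outdir)
    run_report(config, outdir)
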