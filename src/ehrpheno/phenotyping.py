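"""Fusion of ICD codes and classified text mentions into the per-patient
computable phenotype.

A patient with at least one positive in-window occurrence (text or code) is a
confirmed case; one with occurrences but no positive ones is a rejected
presumptive; an adult with a qualifying encounter and zero occurrences is
control-eligible.  The dual-reviewer adjudication rule is implemented even
though the automated pipeline runs single-reviewer by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .nlp_engine import (
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    LABEL_UNCERTAIN,
    MENTION_LABELS,
    Lexicon,
    build_lexicon,
    mentions_to_frame,
    scan_notes,
)

logger = logging.getLogger(__name__)

#: Default phenotype code map: (code_system, normalized code) -> condition.
DEFAULT_CODE_MAP: dict[tuple[str, str], str] = {
    ("ICD9", "797"): "frailty",
    ("ICD10", "R54"): "frailty",
    ("ICD9", "799.4"): "cachexia",
    ("ICD10", "R64"): "cachexia",
    ("ICD10", "M62.84"): "sarcopenia",
}

STATUS_CASE = "confirmed_case"
STATUS_REJECTED = "rejected_presumptive"
STATUS_CONTROL = "control_eligible"
STATUS_INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class StudyWindow:
    """Half-open [start, end) study period."""

    start: date
    end: date

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("study window start must precede end")

    def __contains__(self, d: date) -> bool:
        return self.start <= d < self.end


#: "During 2016-2017" realized as a half-open interval.
DEFAULT_WINDOW = StudyWindow(date(2016, 1, 1), date(2018, 1, 1))


@dataclass(frozen=True)
class Occurrence:
    """One appearance of a phenotype term or code for a patient."""

    patient_id: str
    condition: str
    source: str  # "text" | "code"
    date: date
    label: str  # code occurrences are always positive


@dataclass
class PhenotypeRecord:
    patient_id: str
    status: str
    conditions: frozenset[str]
    detection_source: str | None  # text_only | code_and_text | code_only
    index_date: date | None = None


def normalize_code(code: str) -> str:
    """Trim and uppercase; the dot is retained (exact-match convention)."""
    return str(code).strip().upper()


def detect_code_occurrences(
    diagnoses: pd.DataFrame,
    code_map: Mapping[tuple[str, str], str] | None = None,
    window: StudyWindow | None = None,
    prefix_mode: bool = False,
) -> list[Occurrence]:
    """Turn phenotype ICD diagnosis rows into Occurrences.

    Matching is exact on the normalized (system, code) pair by default ("797"
    does not match "797.0"); ``prefix_mode`` enables prefix matching.  Rows
    with unparseable dates are skipped and counted in the log.
    """
    if code_map is None:
        code_map = DEFAULT_CODE_MAP
    occurrences: list[Occurrence] = []
    skipped = 0
    for row in diagnoses.itertuples(index=False):
        system = str(row.code_system).strip().upper()
        code = normalize_code(row.code)
        condition = None
        if prefix_mode:
            for (sys_, code_), cond in code_map.items():
                if system == sys_ and code.startswith(code_):
                    condition = cond
                    break
        else:
            condition = code_map.get((system, code))
        if condition is None:
            continue
        try:
            d = date.fromisoformat(str(row.date))
        except ValueError:
            skipped += 1
            continue
        if window is not None and d not in window:
            continue
        occurrences.append(
            Occurrence(
                patient_id=str(row.patient_id),
                condition=condition,
                source="code",
                date=d,
                label=LABEL_POSITIVE,
            )
        )
    if skipped:
        logger.warning("detect_code_occurrences: skipped %d rows with malformed dates", skipped)
    return occurrences


def mentions_to_occurrences(mentions: pd.DataFrame, notes: pd.DataFrame) -> list[Occurrence]:
    """Attach note dates to labelled mentions, yielding text Occurrences."""
    if mentions.empty:
        return []
    dated = mentions.merge(notes[["note_id", "note_date"]], on="note_id", how="left")
    out = []
    for row in dated.itertuples(index=False):
        out.append(
            Occurrence(
                patient_id=str(row.patient_id),
                condition=row.condition,
                source="text",
                date=date.fromisoformat(str(row.note_date)),
                label=row.label,
            )
        )
    return out


def adjudicate_labels(label_reviewer1: str, label_reviewer2: str) -> str:
    """Combine two reviewer labels into a final occurrence label.

    Positive wins with (positive, positive) or (positive, uncertain);
    negative with (negative, negative) or (negative, uncertain);
    (uncertain, uncertain) and (positive, negative) give uncertain.
    Symmetric in its arguments.
    """
    for lab in (label_reviewer1, label_reviewer2):
        if lab not in MENTION_LABELS:
            raise ValueError(f"unknown mention label {lab!r}")
    pair = {label_reviewer1, label_reviewer2}
    if pair == {LABEL_POSITIVE} or pair == {LABEL_POSITIVE, LABEL_UNCERTAIN}:
        return LABEL_POSITIVE
    if pair == {LABEL_NEGATIVE} or pair == {LABEL_NEGATIVE, LABEL_UNCERTAIN}:
        return LABEL_NEGATIVE
    return LABEL_UNCERTAIN


def assemble_phenotype(
    patient_id: str,
    occurrences: Sequence[Occurrence],
    had_encounter_in_window: bool,
    age_at_window_start: float,
    window: StudyWindow = DEFAULT_WINDOW,
) -> PhenotypeRecord:
    """Assign one patient's phenotype status from their occurrences.

    Uncertain-final occurrences do not count toward case status (only
    positive ones do), but they do exclude a patient from the control pool.
    """
    for occ in occurrences:
        if occ.patient_id != patient_id:
            raise ValueError("occurrence does not belong to patient")
    if age_at_window_start < 18 or not had_encounter_in_window:
        return PhenotypeRecord(patient_id, STATUS_INELIGIBLE, frozenset(), None)
    in_window = [o for o in occurrences if o.date in window]
    positives = [o for o in in_window if o.label == LABEL_POSITIVE]
    if positives:
        conditions = frozenset(o.condition for o in positives)
        sources = {o.source for o in positives}
        if sources == {"text"}:
            detection = "text_only"
        elif sources == {"code"}:
            detection = "code_only"
        else:
            detection = "code_and_text"
        return PhenotypeRecord(patient_id, STATUS_CASE, conditions, detection)
    if in_window:
        return PhenotypeRecord(patient_id, STATUS_REJECTED, frozenset(), None)
    return PhenotypeRecord(patient_id, STATUS_CONTROL, frozenset(), None)


def assign_index_date(
    record: PhenotypeRecord,
    occurrences: Sequence[Occurrence],
    encounter_dates: Sequence[date],
    window: StudyWindow = DEFAULT_WINDOW,
) -> date:
    """Earliest in-window positive occurrence (cases) or earliest in-window
    encounter (controls)."""
    if record.status == STATUS_CASE:
        dates = [o.date for o in occurrences if o.label == LABEL_POSITIVE and o.date in window]
        if not dates:
            raise ValueError(f"case {record.patient_id} has no in-window positive occurrence")
        return min(dates)
    if record.status == STATUS_CONTROL:
        dates = [d for d in encounter_dates if d in window]
        if not dates:
            raise ValueError(f"control {record.patient_id} has no in-window encounter")
        return min(dates)
    raise ValueError(f"index date undefined for status {record.status}")


def build_phenotypes(
    dataset,
    lexicon: Lexicon | None = None,
    window: StudyWindow = DEFAULT_WINDOW,
    code_map: Mapping[tuple[str, str], str] | None = None,
    min_age: int = 18,
) -> tuple[pd.DataFrame, pd.DataFrame, list[Occurrence]]:
    """Run text detection + code detection + assembly over a whole dataset.

    Returns (phenotypes, mentions, occurrences).  Phenotype rows carry the
    phenotypes.csv contract: patient_id, status, conditions (semicolon list),
    detection_source, index_date.
    """
    if lexicon is None:
        lexicon = build_lexicon()
    mentions = scan_notes(dataset.notes.to_dict("records"), lexicon)
    mentions_df = mentions_to_frame(mentions)
    occurrences = mentions_to_occurrences(mentions_df, dataset.notes)
    occurrences += detect_code_occurrences(dataset.diagnoses, code_map=code_map, window=window)

    by_patient: dict[str, list[Occurrence]] = {}
    for occ in occurrences:
        by_patient.setdefault(occ.patient_id, []).append(occ)
    enc = dataset.encounters
    enc_dates: dict[str, list[date]] = {}
    for row in enc.itertuples(index=False):
        d = date.fromisoformat(str(row.encounter_date))
        enc_dates.setdefault(str(row.patient_id), []).append(d)

    rows = []
    for row in dataset.patients.itertuples(index=False):
        pid = str(row.patient_id)
        age = window.start.year - int(row.birth_year)
        p_enc = [d for d in enc_dates.get(pid, []) if d in window]
        record = assemble_phenotype(pid, by_patient.get(pid, []), bool(p_enc), age, window)
        index_date = None
        if record.status in (STATUS_CASE, STATUS_CONTROL):
            index_date = assign_index_date(record, by_patient.get(pid, []), p_enc, window)
        rows.append(
            {
                "patient_id": pid,
                "status": record.status,
                "conditions": ";".join(sorted(record.conditions)),
                "detection_source": record.detection_source or "",
                "index_date": index_date.isoformat() if index_date else "",
            }
        )
    phenotypes = pd.DataFrame(
        rows, columns=["patient_id", "status", "conditions", "detection_source", "index_date"]
    )
    logger.info(
        "phenotyping: %d cases, %d rejected presumptive, %d control-eligible, %d ineligible",
        (phenotypes["status"] == STATUS_CASE).sum(),
        (phenotypes["status"] == STATUS_REJECTED).sum(),
        (phenotypes["status"] == STATUS_CONTROL).sum(),
        (phenotypes["status"] == STATUS_INELIGIBLE).sum(),
    )
    return phenotypes, mentions_df, occurrences
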