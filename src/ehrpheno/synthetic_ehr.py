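"""Synthetic EHR generator with planted ground truth.

Emulates the statistical structure of a multi-system EHR extract for a
case-control study of clinician-documented sarcopenia, cachexia and frailty:

* a small fraction of patients carry condition terms in their notes, with a
  realistic overlap pattern between the three conditions;
* most term uses are positive; a per-condition minority are negated or refer
  to another person (a "rejected presumptive" patient has only such uses);
* only ~13.6% of true cases also receive a phenotype ICD code, and codes are
  planted only alongside text (code-only detection never occurs by default);
* cases carry more comorbidity codes, lower BMI/albumin, more
  hospitalizations and more appetite-stimulant dispensings than controls,
  with configurable control prevalences and target odds ratios.

Note text is assembled from a fixed library of clinic-note sentence
templates, so the rule-based detector can be validated against planted spans
exactly.  Every random draw flows through one seeded generator: the same
config yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .nlp_engine import CONDITIONS, DEFAULT_CANONICAL_FORMS, Lexicon, build_lexicon

#: Phenotype ICD codes: condition -> [(code_system, code), ...]
PHENOTYPE_CODES: dict[str, tuple[tuple[str, str], ...]] = {
    "sarcopenia": (("ICD10", "M62.84"),),
    "cachexia": (("ICD9", "799.4"), ("ICD10", "R64")),
    "frailty": (("ICD9", "797"), ("ICD10", "R54")),
}

_MIX_KEYS = (
    "sarcopenia",
    "cachexia",
    "frailty",
    "sarcopenia+cachexia",
    "sarcopenia+frailty",
    "cachexia+frailty",
    "sarcopenia+cachexia+frailty",
)

# Condition-set distribution among cases, from the observed cross-tabulation
# of a statewide cohort (subset counts over 9594 cases).
_DEFAULT_MIX = {
    "sarcopenia": 89 / 9594,
    "cachexia": 2607 / 9594,
    "frailty": 5402 / 9594,
    "sarcopenia+cachexia": 33 / 9594,
    "sarcopenia+frailty": 57 / 9594,
    "cachexia+frailty": 1273 / 9594,
    "sarcopenia+cachexia+frailty": 133 / 9594,
}


class ComorbiditySpec(BaseModel):
    """Control-arm prevalence, target case-control odds ratio and the ICD-10
    codes planted when the flag is drawn."""

    control_prevalence: float = Field(ge=0.0, le=1.0)
    odds_ratio: float = Field(gt=0.0)
    icd10_codes: tuple[str, ...]


class LabSpec(BaseModel):
    units: str
    dist: Literal["normal", "lognormal"]
    case_median: float
    case_q1: float
    case_q3: float
    control_median: float
    control_q1: float
    control_q3: float
    case_measured: float = Field(ge=0.0, le=1.0)
    control_measured: float = Field(ge=0.0, le=1.0)


class MedSpec(BaseModel):
    case_prob: float = Field(ge=0.0, le=1.0)
    control_prob: float = Field(ge=0.0, le=1.0)


def _default_comorbidities() -> dict[str, ComorbiditySpec]:
    # Control prevalences and odds ratios patterned on the observed
    # case-control contrasts; codes chosen so both the comorbidity flagger
    # and the Charlson index respond to them.
    spec = {
        "diabetes_with_complication": (0.035, 4.33, ("E11.21", "E11.40")),
        "diabetes_without_complication": (0.161, 1.80, ("E11.9", "E10.9")),
        "hypertension": (0.377, 3.26, ("I10",)),
        "cardiovascular_disease": (0.403, 4.49, ("I25.10", "I25.10", "I50.9", "I21.4")),
        "peripheral_vascular_disease": (0.061, 3.76, ("I73.9", "I70.0")),
        "ckd_stage_3": (0.049, 2.42, ("N18.3",)),
        "ckd_stage_4": (0.016, 4.51, ("N18.4",)),
        "ckd_stage_5": (0.007, 8.39, ("N18.5", "N18.6")),
        "any_malignancy": (0.099, 4.08, ("C34.90", "C18.9", "C50.911")),
        "liver_disease": (0.026, 4.41, ("K74.60", "K70.30")),
        "depression": (0.018, 9.32, ("F32.9", "F33.1")),
        "aids": (0.002, 7.69, ("B20",)),
        "neurologic_conditions": (0.215, 7.47, ("G30.9", "I63.9", "G20", "G62.9")),
        "fractures": (0.033, 3.78, ("S72.001", "S22.00")),
        "osteoporosis": (0.063, 3.03, ("M81.0",)),
    }
    return {
        k: ComorbiditySpec(control_prevalence=p0, odds_ratio=orr, icd10_codes=codes)
        for k, (p0, orr, codes) in spec.items()
    }


#: CKD stages are drawn as one mutually exclusive categorical so the nested
#: stage flags stay consistent (stage 4 implies stages 3-5).
EXCLUSIVE_COMORBIDITY_GROUPS: dict[str, tuple[str, ...]] = {
    "ckd": ("ckd_stage_3", "ckd_stage_4", "ckd_stage_5"),
}


def _default_labs() -> dict[str, LabSpec]:
    def mk(units, dist, cm, cq1, cq3, km, kq1, kq3, pc, pk):
        return LabSpec(
            units=units, dist=dist,
            case_median=cm, case_q1=cq1, case_q3=cq3,
            control_median=km, control_q1=kq1, control_q3=kq3,
            case_measured=pc, control_measured=pk,
        )

    return {
        "bmi": mk("kg/m2", "lognormal", 22.1, 18.9, 26.2, 28.1, 24.6, 32.5, 0.829, 0.510),
        "weight": mk("kg", "lognormal", 60.7, 50.5, 73.8, 79.5, 65.9, 94.8, 0.900, 0.626),
        "albumin": mk("mg/dl", "normal", 3.6, 3.1, 4.0, 4.1, 3.8, 4.3, 0.905, 0.564),
        "prealbumin": mk("mg/dl", "normal", 14.0, 9.0, 20.0, 20.0, 12.0, 25.0, 0.139, 0.011),
        "hba1c": mk("%", "lognormal", 5.9, 5.5, 6.7, 6.0, 5.6, 6.7, 0.352, 0.169),
    }


def _default_meds() -> dict[str, MedSpec]:
    return {
        "glucocorticoids": MedSpec(case_prob=0.125, control_prob=0.155),
        "dronabinol": MedSpec(case_prob=0.0072, control_prob=0.0005),
        "megestrol": MedSpec(case_prob=0.0097, control_prob=0.0020),
        "caloric_supplement": MedSpec(case_prob=0.0031, control_prob=0.0013),
        "testosterone": MedSpec(case_prob=0.0015, control_prob=0.0038),
    }


class GeneratorConfig(BaseModel):
    """Full specification of one synthetic cohort.

    All probabilities live in [0, 1]; the condition mix is an explicit
    7-cell joint distribution over nonempty subsets of
    {sarcopenia, cachexia, frailty} and must sum to 1.
    """

    n_patients: int = Field(default=20000, ge=0)
    study_start: date = date(2016, 1, 1)
    study_end: date = date(2018, 1, 1)  # half-open [start, end)
    case_prevalence: float = Field(default=0.05, ge=0.0, le=1.0)
    rejected_presumptive_rate: float = Field(default=0.067, ge=0.0, lt=1.0)
    condition_mix: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_MIX))
    positive_use_rate: dict[str, float] = Field(
        default_factory=lambda: {"sarcopenia": 0.97, "cachexia": 0.90, "frailty": 0.95}
    )
    icd_given_text: float = Field(default=0.136, ge=0.0, le=1.0)
    extra_code_rate: float = Field(default=0.031, ge=0.0, le=1.0)
    misspelling_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    mentions_per_condition_mean: float = Field(default=2.0, ge=1.0)
    other_person_share: float = Field(default=0.5, ge=0.0, le=1.0)
    comorbidity_model: dict[str, ComorbiditySpec] = Field(default_factory=_default_comorbidities)
    lab_model: dict[str, LabSpec] = Field(default_factory=_default_labs)
    med_model: dict[str, MedSpec] = Field(default_factory=_default_meds)
    female_share: float = Field(default=0.59, ge=0.0, le=1.0)
    race_probs: dict[str, float] = Field(
        default_factory=lambda: {"black": 0.10, "white": 0.69, "other": 0.21}
    )
    age_median: float = 74.9
    age_q1: float = 62.2
    age_q3: float = 84.8
    ambulatory_encounters_mean: float = Field(default=2.0, ge=1.0)
    hospitalization_mean_case: float = Field(default=2.5, ge=0.0)
    hospitalization_mean_control: float = Field(default=0.15, ge=0.0)
    background_notes_mean: float = Field(default=1.0, ge=0.0)
    rng_seed: int = 0

    @field_validator("positive_use_rate")
    @classmethod
    def _check_rates(cls, v):
        for cond, r in v.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if not 0.0 < r <= 1.0:
                raise ValueError(f"positive_use_rate[{cond!r}]={r} outside (0, 1]")
        return v

    @field_validator("condition_mix")
    @classmethod
    def _check_mix(cls, v):
        for key, p in v.items():
            if key not in _MIX_KEYS:
                raise ValueError(f"unknown condition-mix cell {key!r}")
            if p < 0:
                raise ValueError(f"condition_mix[{key!r}] negative")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"condition_mix must sum to 1 (got {total})")
        return v

    @field_validator("race_probs")
    @classmethod
    def _check_race(cls, v):
        if set(v) != {"black", "white", "other"} or abs(sum(v.values()) - 1.0) > 1e-6:
            raise ValueError("race_probs must cover black/white/other and sum to 1")
        return v

    @model_validator(mode="after")
    def _check_window(self):
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls.model_validate(payload)


def case_probability(control_prevalence: float, odds_ratio: float) -> float:
    """Invert the odds-ratio definition: the case-arm Bernoulli probability
    p1 with odds(p1) = OR * odds(p0)."""
    p0 = control_prevalence
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"control prevalence {p0} outside [0, 1]")
    if odds_ratio <= 0 or not math.isfinite(odds_ratio):
        raise ValueError(f"odds ratio must be finite and positive, got {odds_ratio}")
    if p0 == 0.0:
        return 0.0
    p1 = odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)
    if p1 > 1.0 + 1e-12:
        raise ValueError(f"implied case probability {p1} exceeds 1")
    return min(p1, 1.0)


def sample_comorbidities(
    is_case: bool,
    comorbidity_model: Mapping[str, ComorbiditySpec],
    rng: np.random.Generator,
) -> dict[str, bool]:
    """Draw one patient's comorbidity flags.

    Flags are independent Bernoulli draws at the control prevalence (controls)
    or the OR-implied case probability (cases), except CKD stages, which are
    drawn as one exclusive categorical.
    """
    flags: dict[str, bool] = {}
    exclusive = {m for grp in EXCLUSIVE_COMORBIDITY_GROUPS.values() for m in grp}
    for name in sorted(comorbidity_model):
        if name in exclusive:
            continue
        spec = comorbidity_model[name]
        p = case_probability(spec.control_prevalence, spec.odds_ratio) if is_case else spec.control_prevalence
        flags[name] = bool(rng.random() < p)
    for members in EXCLUSIVE_COMORBIDITY_GROUPS.values():
        present = [m for m in members if m in comorbidity_model]
        probs = [
            case_probability(comorbidity_model[m].control_prevalence, comorbidity_model[m].odds_ratio)
            if is_case
            else comorbidity_model[m].control_prevalence
            for m in present
        ]
        if sum(probs) > 1.0:
            raise ValueError(f"exclusive group probabilities sum to {sum(probs)} > 1")
        u = rng.random()
        acc = 0.0
        chosen = None
        for m, p in zip(present, probs):
            acc += p
            if u < acc:
                chosen = m
                break
        for m in present:
            flags[m] = m == chosen
    return flags


# ---------------------------------------------------------------------------
# Note templates.  {term} is the condition slot.  Positive templates contain
# no negation trigger, hedge, or kinship cue; negated templates put a trigger
# within five tokens before (or after) the slot; other-person templates name a
# non-patient subject in the same sentence.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoteTemplate:
    text: str
    form_kind: Literal["noun", "adjective"]


TEMPLATES: dict[str, tuple[NoteTemplate, ...]] = {
    "positive": (
        NoteTemplate("Assessment notes significant {term} with ongoing weight loss.", "noun"),
        NoteTemplate("Exam reveals {term} and generalized weakness.", "noun"),
        NoteTemplate("Longstanding {term} documented in the problem list.", "noun"),
        NoteTemplate("Nutrition consult placed for {term} and poor oral intake.", "noun"),
        NoteTemplate("Clinical picture consistent with {term}.", "noun"),
        NoteTemplate("Progressive {term} noted since the last visit.", "noun"),
        NoteTemplate("Plan to address {term} with resistance exercise and protein supplementation.", "noun"),
        NoteTemplate("Physical therapy evaluating deconditioning related to {term}.", "noun"),
        NoteTemplate("The patient is {term} and requires assistance with transfers.", "adjective"),
        NoteTemplate("Elderly patient, appears {term} and deconditioned.", "adjective"),
        NoteTemplate("She remains {term} despite aggressive therapy.", "adjective"),
        NoteTemplate("He looks markedly {term} compared to prior visits.", "adjective"),
    ),
    "negated": (
        NoteTemplate("There is no evidence of {term} at this time.", "noun"),
        NoteTemplate("Patient denies {term} or recent weight loss.", "noun"),
        NoteTemplate("Workup negative for {term}.", "noun"),
        NoteTemplate("No {term} identified on review of systems.", "noun"),
        NoteTemplate("He is without {term} or malnutrition.", "noun"),
        NoteTemplate("He is not {term}.", "adjective"),
        NoteTemplate("The patient is not {term} at this time.", "adjective"),
        NoteTemplate("She does not appear {term} today.", "adjective"),
    ),
    "other_person": (
        NoteTemplate("Her mother has advanced {term}.", "noun"),
        NoteTemplate("His sister was recently diagnosed with {term}.", "noun"),
        NoteTemplate("Family history includes a father with {term}.", "noun"),
        NoteTemplate("She spends most days caring for her sick, {term} mother.", "adjective"),
        NoteTemplate("His {term} wife requires full time care.", "adjective"),
        NoteTemplate("Patient's brother is {term} and lives nearby.", "adjective"),
    ),
}

#: Filler sentences for background notes; none contains a lexicon form.
BACKGROUND_SENTENCES = (
    "Follow up visit for routine care.",
    "Medications reviewed and reconciled.",
    "Blood pressure well controlled on current regimen.",
    "Patient counseled on diet and activity.",
    "Laboratory results reviewed with the patient.",
    "Immunizations are up to date.",
    "Return to clinic in three months.",
    "Sleep and mood are stable.",
    "Chronic issues managed per prior plan.",
    "Reviewed home safety and fall precautions.",
)

_USE_KINDS = ("positive", "negated", "other_person")
#: Expected classifier label for each planted use kind.
EXPECTED_LABEL = {"positive": "positive", "negated": "negative", "other_person": "negative"}

_default_lexicon: Lexicon | None = None


def _planting_lexicon() -> Lexicon:
    global _default_lexicon
    if _default_lexicon is None:
        _default_lexicon = build_lexicon(DEFAULT_CANONICAL_FORMS, max_edit_distance=1)
    return _default_lexicon


@dataclass
class PlantedNote:
    text: str
    start: int
    end: int
    form: str
    condition: str
    use_kind: str
    expected_label: str
    misspelled: bool


def _surface_form(condition: str, form_kind: str) -> str:
    noun, adjective = DEFAULT_CANONICAL_FORMS[condition]
    return noun if form_kind == "noun" else adjective


def _misspell(form: str, condition: str, rng: np.random.Generator) -> str:
    """One random single-character edit that the lexicon still detects."""
    lex = _planting_lexicon()
    for _ in range(100):
        op = rng.integers(4)
        i = int(rng.integers(len(form)))
        c = chr(ord("a") + int(rng.integers(26)))
        if op == 0:  # substitution
            cand = form[:i] + c + form[i + 1 :]
        elif op == 1:  # deletion
            cand = form[:i] + form[i + 1 :]
        elif op == 2:  # insertion
            cand = form[:i] + c + form[i:]
        else:  # adjacent transposition
            if i >= len(form) - 1:
                continue
            cand = form[:i] + form[i + 1] + form[i] + form[i + 2 :]
        if cand != form and lex.condition_of(cand) == condition:
            return cand
    return form


def plant_mentions(
    template: NoteTemplate | None,
    condition: str,
    use_kind: str,
    misspell: bool,
    rng: np.random.Generator,
) -> PlantedNote:
    """Fill one sentence template with a (possibly misspelled) surface form.

    Returns the sentence text plus the exact character span of the planted
    term and the label the rule-based classifier is expected to produce.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if use_kind not in _USE_KINDS:
        raise ValueError(f"unknown use kind {use_kind!r}")
    if template is None:
        pool = TEMPLATES[use_kind]
        if misspell:
            # only forms longer than 5 characters can be misspelled detectably
            pool = tuple(
                t for t in pool if len(_surface_form(condition, t.form_kind)) > 5
            ) or TEMPLATES[use_kind]
        template = pool[int(rng.integers(len(pool)))]
    form = _surface_form(condition, template.form_kind)
    misspelled = False
    if misspell and len(form) > 5:
        new_form = _misspell(form, condition, rng)
        misspelled = new_form != form
        form = new_form
    prefix = template.text.split("{term}")[0]
    text = template.text.format(term=form)
    start = len(prefix)
    return PlantedNote(
        text=text,
        start=start,
        end=start + len(form),
        form=form,
        condition=condition,
        use_kind=use_kind,
        expected_label=EXPECTED_LABEL[use_kind],
        misspelled=misspelled,
    )


# ---------------------------------------------------------------------------
# Dataset containers
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "birth_year", "sex", "race"]
_ENCOUNTER_COLS = ["patient_id", "encounter_date", "is_hospitalization"]
_NOTE_COLS = ["note_id", "patient_id", "note_date", "text"]
_DIAGNOSIS_COLS = ["patient_id", "code_system", "code", "date"]
_LAB_COLS = ["patient_id", "analyte", "value", "units", "date"]
_MED_COLS = ["patient_id", "drug_class", "dispense_date"]


@dataclass
class EHRDataset:
    """The six tables of a synthetic (or ingested) EHR extract."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    notes: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(outdir / "patients.csv", index=False)
        self.encounters.to_csv(outdir / "encounters.csv", index=False)
        self.diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
        self.labs.to_csv(outdir / "labs.csv", index=False)
        self.medications.to_csv(outdir / "medications.csv", index=False)
        with open(outdir / "notes.jsonl", "w") as fh:
            for row in self.notes.itertuples(index=False):
                fh.write(
                    json.dumps(
                        {
                            "note_id": row.note_id,
                            "patient_id": row.patient_id,
                            "note_date": row.note_date,
                            "text": row.text,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )

    @classmethod
    def read(cls, outdir: str | Path) -> "EHRDataset":
        outdir = Path(outdir)
        notes = pd.read_json(outdir / "notes.jsonl", lines=True, dtype={"note_id": str, "patient_id": str})
        if notes.empty:
            notes = pd.DataFrame(columns=_NOTE_COLS)
        else:
            notes["note_date"] = notes["note_date"].astype(str)
        return cls(
            patients=pd.read_csv(outdir / "patients.csv", dtype={"patient_id": str}),
            encounters=pd.read_csv(outdir / "encounters.csv", dtype={"patient_id": str}),
            notes=notes[_NOTE_COLS] if len(notes) else notes,
            diagnoses=pd.read_csv(outdir / "diagnoses.csv", dtype={"patient_id": str, "code": str}),
            labs=pd.read_csv(outdir / "labs.csv", dtype={"patient_id": str}),
            medications=pd.read_csv(outdir / "medications.csv", dtype={"patient_id": str}),
        )


@dataclass
class PlantedTruth:
    """Ground truth for a synthetic cohort: per-patient status/conditions/
    comorbidities/index date and per-mention spans with expected labels."""

    patients: dict[str, dict]
    mentions: list[dict]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"patients": self.patients, "mentions": self.mentions}, sort_keys=True, indent=0)
        )

    @classmethod
    def read(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(patients=payload["patients"], mentions=payload["mentions"])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _rejected_condition_weights(config: GeneratorConfig) -> dict[str, float]:
    """Weights for the (single) condition of a rejected-presumptive patient.

    Chosen so that the patient-level positive-use rate of condition c,
    confirmed_c / (confirmed_c + rejected_c), approximates the configured
    rate: weight ∝ m_c (1-r_c)/r_c with m_c the case marginal.  Normalised,
    because the three targets plus the overall rejected rate are not jointly
    attainable exactly.
    """
    marginals = {c: 0.0 for c in CONDITIONS}
    for key, p in config.condition_mix.items():
        for c in key.split("+"):
            marginals[c] += p
    w = {
        c: marginals[c] * (1.0 - config.positive_use_rate[c]) / config.positive_use_rate[c]
        for c in CONDITIONS
    }
    total = sum(w.values())
    if total == 0:
        return {c: 1.0 / len(CONDITIONS) for c in CONDITIONS}
    return {c: v / total for c, v in w.items()}


def _random_dates(rng: np.random.Generator, n: int, start: date, end: date) -> np.ndarray:
    days = (end - start).days
    offsets = rng.integers(0, days, size=n)
    base = np.datetime64(start.isoformat())
    return (base + offsets.astype("timedelta64[D]")).astype(str)


def generate_cohort(config: GeneratorConfig) -> tuple[EHRDataset, PlantedTruth]:
    """Generate one synthetic cohort with planted ground truth.

    Deterministic: identical config (including seed) gives byte-identical
    output files.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_patients
    start, end = config.study_start, config.study_end

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.female_share, "female", "male")
    race_names = ("black", "white", "other")
    race = rng.choice(race_names, size=n, p=[config.race_probs[r] for r in race_names])
    age_sd = (config.age_q3 - config.age_q1) / 1.3490  # quartile spread of a normal
    age = np.clip(rng.normal(config.age_median, age_sd, size=n), 18.0, 102.0)
    birth_year = start.year - np.floor(age).astype(int)

    p_conf = config.case_prevalence
    rr = config.rejected_presumptive_rate
    p_rej = p_conf * rr / (1.0 - rr) if p_conf > 0 else 0.0
    u = rng.random(n)
    status = np.where(u < p_conf, "case", np.where(u < p_conf + p_rej, "rejected_presumptive", "control"))

    mix_keys = [k for k in _MIX_KEYS if config.condition_mix.get(k, 0.0) > 0]
    mix_probs = np.array([config.condition_mix[k] for k in mix_keys])
    mix_probs = mix_probs / mix_probs.sum()
    rej_weights = _rejected_condition_weights(config)

    condition_sets: list[tuple[str, ...]] = []
    for i in range(n):
        if status[i] == "case":
            key = mix_keys[int(rng.choice(len(mix_keys), p=mix_probs))]
            condition_sets.append(tuple(key.split("+")))
        elif status[i] == "rejected_presumptive":
            c = rng.choice(CONDITIONS, p=[rej_weights[c] for c in CONDITIONS])
            condition_sets.append((str(c),))
        else:
            condition_sets.append(())

    # --- encounters -------------------------------------------------------
    is_case = status == "case"
    amb_counts = 1 + rng.poisson(max(config.ambulatory_encounters_mean - 1.0, 0.0), size=n)
    hosp_counts = rng.poisson(
        np.where(is_case, config.hospitalization_mean_case, config.hospitalization_mean_control)
    )
    enc_pid = np.repeat(patient_ids, amb_counts + hosp_counts)
    enc_hosp = np.concatenate(
        [np.r_[np.zeros(a, dtype=bool), np.ones(h, dtype=bool)] for a, h in zip(amb_counts, hosp_counts)]
    ) if n else np.array([], dtype=bool)
    enc_dates = _random_dates(rng, len(enc_pid), start, end)
    encounters = pd.DataFrame(
        {"patient_id": enc_pid, "encounter_date": enc_dates, "is_hospitalization": enc_hosp},
        columns=_ENCOUNTER_COLS,
    )
    first_encounter = (
        encounters.groupby("patient_id")["encounter_date"].min() if n else pd.Series(dtype=str)
    )

    # --- comorbidities and diagnoses --------------------------------------
    exclusive = {m for grp in EXCLUSIVE_COMORBIDITY_GROUPS.values() for m in grp}
    comorbidity_flags: dict[str, np.ndarray] = {}
    for name in sorted(config.comorbidity_model):
        if name in exclusive:
            continue
        spec = config.comorbidity_model[name]
        p1 = case_probability(spec.control_prevalence, spec.odds_ratio)
        p = np.where(is_case, p1, spec.control_prevalence)
        comorbidity_flags[name] = rng.random(n) < p
    for members in EXCLUSIVE_COMORBIDITY_GROUPS.values():
        present = [m for m in members if m in config.comorbidity_model]
        if not present:
            continue
        probs = np.stack(
            [
                np.where(
                    is_case,
                    case_probability(
                        config.comorbidity_model[m].control_prevalence,
                        config.comorbidity_model[m].odds_ratio,
                    ),
                    config.comorbidity_model[m].control_prevalence,
                )
                for m in present
            ]
        )
        if np.any(probs.sum(axis=0) > 1.0):
            raise ValueError("exclusive comorbidity group probabilities sum above 1")
        uu = rng.random(n)
        cum = np.cumsum(probs, axis=0)
        chosen = np.full(n, -1)
        for j in range(len(present) - 1, -1, -1):
            chosen = np.where(uu < cum[j], j, chosen)
        for j, m in enumerate(present):
            comorbidity_flags[m] = chosen == j

    diag_rows: list[tuple[str, str, str, str]] = []
    for name in sorted(comorbidity_flags):
        codes = config.comorbidity_model[name].icd10_codes
        idx = np.nonzero(comorbidity_flags[name])[0]
        picked = rng.integers(0, len(codes), size=len(idx))
        dates = _random_dates(rng, len(idx), start, end)
        for i, k, d in zip(idx, picked, dates):
            diag_rows.append((patient_ids[i], "ICD10", codes[k], d))
    # benign noise codes so that not every diagnosis maps to a category
    noise_mask = rng.random(n) < 0.5
    noise_idx = np.nonzero(noise_mask)[0]
    noise_code = rng.integers(0, 2, size=len(noise_idx))
    noise_dates = _random_dates(rng, len(noise_idx), start, end)
    for i, k, d in zip(noise_idx, noise_code, noise_dates):
        diag_rows.append((patient_ids[i], "ICD10", ("Z00.00", "J06.9")[k], d))

    # --- notes and planted mentions ---------------------------------------
    note_rows: list[tuple[str, str, str, str]] = []
    truth_mentions: list[dict] = []
    positive_dates: dict[str, list[str]] = {}
    note_counter = 0

    def new_note(pid: str, text: str, note_date: str) -> str:
        nonlocal note_counter
        nid = f"N{note_counter:07d}"
        note_counter += 1
        note_rows.append((nid, pid, note_date, text))
        return nid

    bg_counts = 1 + rng.poisson(config.background_notes_mean, size=n)
    mean_mentions = config.mentions_per_condition_mean
    geo_p = 1.0 / mean_mentions

    for i in range(n):
        pid = patient_ids[i]
        for _ in range(bg_counts[i]):
            k = int(rng.integers(2, 4))
            sents = [BACKGROUND_SENTENCES[int(rng.integers(len(BACKGROUND_SENTENCES)))] for _ in range(k)]
            new_note(pid, " ".join(sents), str(_random_dates(rng, 1, start, end)[0]))
        if status[i] == "control":
            continue
        for condition in condition_sets[i]:
            n_mentions = int(rng.geometric(geo_p))
            rate = config.positive_use_rate[condition]
            if status[i] == "case":
                for _ in range(100):
                    labels = rng.random(n_mentions) < rate
                    if labels.any():
                        break
                else:
                    labels = np.ones(n_mentions, dtype=bool)
            else:
                labels = np.zeros(n_mentions, dtype=bool)
            for pos in labels:
                if pos:
                    use_kind = "positive"
                elif rng.random() < config.other_person_share:
                    use_kind = "other_person"
                else:
                    use_kind = "negated"
                misspell = bool(rng.random() < config.misspelling_rate)
                planted = plant_mentions(None, condition, use_kind, misspell, rng)
                # wrap the mention sentence with background filler
                n_before = int(rng.integers(0, 3))
                prefix = " ".join(
                    BACKGROUND_SENTENCES[int(rng.integers(len(BACKGROUND_SENTENCES)))]
                    for _ in range(n_before)
                )
                if prefix:
                    prefix += " "
                text = prefix + planted.text
                note_date = str(_random_dates(rng, 1, start, end)[0])
                nid = new_note(pid, text, note_date)
                truth_mentions.append(
                    {
                        "note_id": nid,
                        "patient_id": str(pid),
                        "condition": condition,
                        "start": len(prefix) + planted.start,
                        "end": len(prefix) + planted.end,
                        "form": planted.form,
                        "label": planted.expected_label,
                        "use_kind": use_kind,
                        "misspelled": planted.misspelled,
                    }
                )
                if pos:
                    positive_dates.setdefault(pid, []).append(note_date)

    # --- phenotype ICD codes (cases only, alongside text) ------------------
    # icd_given_text is a patient-level probability; a coded case gets a code
    # for one of its conditions, plus each further condition at the (small)
    # extra_code_rate, so multi-code patients stay rare.
    for i in range(n):
        if status[i] != "case":
            continue
        pid = patient_ids[i]
        if rng.random() >= config.icd_given_text:
            continue
        conds = list(condition_sets[i])
        order = rng.permutation(len(conds))
        coded = [conds[order[0]]]
        coded += [conds[j] for j in order[1:] if rng.random() < config.extra_code_rate]
        for condition in coded:
            options = PHENOTYPE_CODES[condition]
            system, code = options[int(rng.integers(len(options)))]
            d = str(_random_dates(rng, 1, start, end)[0])
            diag_rows.append((pid, system, code, d))
            positive_dates.setdefault(pid, []).append(d)

    # --- planted index dates ----------------------------------------------
    index_dates: dict[str, str | None] = {}
    for i in range(n):
        pid = patient_ids[i]
        if status[i] == "case":
            index_dates[pid] = min(positive_dates[pid])
        else:
            index_dates[pid] = str(first_encounter.loc[pid])

    # --- labs ---------------------------------------------------------------
    lab_rows: list[tuple[str, str, float, str, str]] = []
    lab_values: dict[str, np.ndarray] = {}
    lab_measured: dict[str, np.ndarray] = {}
    for analyte in sorted(config.lab_model):
        spec = config.lab_model[analyte]
        measured = rng.random(n) < np.where(is_case, spec.case_measured, spec.control_measured)
        if spec.dist == "normal":
            sd_case = (spec.case_q3 - spec.case_q1) / 1.3490
            sd_ctrl = (spec.control_q3 - spec.control_q1) / 1.3490
            vals = rng.normal(
                np.where(is_case, spec.case_median, spec.control_median),
                np.where(is_case, sd_case, sd_ctrl),
            )
            vals = np.maximum(vals, 0.1)
        else:
            sig_case = math.log(spec.case_q3 / spec.case_q1) / 1.3490
            sig_ctrl = math.log(spec.control_q3 / spec.control_q1) / 1.3490
            vals = np.exp(
                rng.normal(
                    np.where(is_case, math.log(spec.case_median), math.log(spec.control_median)),
                    np.where(is_case, sig_case, sig_ctrl),
                )
            )
        vals = np.round(vals, 2)
        dates = _random_dates(rng, n, start, end)
        lab_values[analyte] = vals
        lab_measured[analyte] = measured
        for i in np.nonzero(measured)[0]:
            lab_rows.append((patient_ids[i], analyte, float(vals[i]), spec.units, dates[i]))
    # height consistent with planted weight and BMI, so BMI recomputation
    # from height/weight agrees with the recorded BMI
    if "weight" in lab_values and "bmi" in lab_values:
        both = lab_measured["weight"] & lab_measured["bmi"]
        heights = np.round(np.sqrt(lab_values["weight"] / lab_values["bmi"]) * 100.0, 1)
        dates = _random_dates(rng, n, start, end)
        for i in np.nonzero(both)[0]:
            lab_rows.append((patient_ids[i], "height", float(heights[i]), "cm", dates[i]))

    # --- medications --------------------------------------------------------
    med_rows: list[tuple[str, str, str]] = []
    for drug in sorted(config.med_model):
        spec = config.med_model[drug]
        p = np.where(is_case, spec.case_prob, spec.control_prob)
        dispensed = rng.random(n) < p
        for i in np.nonzero(dispensed)[0]:
            pid = patient_ids[i]
            idx_date = date.fromisoformat(index_dates[pid])
            span = (end - idx_date).days
            d = idx_date + timedelta(days=int(rng.integers(0, max(span, 1))))
            med_rows.append((pid, drug, d.isoformat()))

    # --- assemble -----------------------------------------------------------
    patients = pd.DataFrame(
        {"patient_id": patient_ids, "birth_year": birth_year, "sex": sex, "race": race},
        columns=_PATIENT_COLS,
    )
    notes = pd.DataFrame(note_rows, columns=_NOTE_COLS)
    diagnoses = pd.DataFrame(diag_rows, columns=_DIAGNOSIS_COLS)
    labs = pd.DataFrame(lab_rows, columns=_LAB_COLS)
    medications = pd.DataFrame(med_rows, columns=_MED_COLS)
    for df, cols in (
        (encounters, ["patient_id", "encounter_date", "is_hospitalization"]),
        (diagnoses, ["patient_id", "code_system", "code", "date"]),
        (labs, ["patient_id", "analyte", "date"]),
        (medications, ["patient_id", "drug_class", "dispense_date"]),
    ):
        df.sort_values(cols, kind="stable", inplace=True, ignore_index=True)

    truth_patients = {
        str(patient_ids[i]): {
            "status": str(status[i]),
            "conditions": sorted(condition_sets[i]),
            "comorbidities": {k: bool(v[i]) for k, v in sorted(comorbidity_flags.items())},
            "index_date": index_dates[patient_ids[i]] if status[i] != "rejected_presumptive" else None,
        }
        for i in range(n)
    }
    dataset = EHRDataset(
        patients=patients,
        encounters=encounters,
        notes=notes,
        diagnoses=diagnoses,
        labs=labs,
        medications=medications,
    )
    return dataset, PlantedTruth(patients=truth_patients, mentions=truth_mentions)
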