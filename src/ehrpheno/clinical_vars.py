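"""Derivation of the analysis variables: comorbidity flags, Charlson index,
index-anchored labs and anthropometrics, hospitalization counts, and
post-index medication flags.

The ICD->category mappings ship as editable JSON package data.  The Charlson
index follows the Quan (2005) ICD-9/ICD-10 coding algorithms with the
original weights and the standard hierarchy rules (a severe form supersedes
its mild counterpart).  Missing labs stay missing — in EHR data absence of a
value cannot be distinguished from a negative finding, so nothing is imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phenotyping import StudyWindow, normalize_code

MEDICATION_CLASSES = (
    "glucocorticoids",
    "dronabinol",
    "megestrol",
    "caloric_supplement",
    "testosterone",
)


def _load_data(name: str) -> dict:
    with resources.files("ehrpheno.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class CharlsonMap:
    """Category -> (weight, ICD-9 prefixes, ICD-10 prefixes) plus hierarchy
    pairs (severe supersedes mild)."""

    categories: Mapping[str, dict]
    hierarchy: Sequence[tuple[str, str]]

    @classmethod
    def default(cls) -> "CharlsonMap":
        payload = _load_data("charlson_quan.json")
        return cls(
            categories=payload["categories"],
            hierarchy=[tuple(pair) for pair in payload["hierarchy"]],
        )


def default_comorbidity_categories() -> dict:
    return _load_data("comorbidity_categories.json")


def _codes_by_system(diagnoses: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {"ICD9": [], "ICD10": []}
    if diagnoses.empty:
        return out
    for row in diagnoses.itertuples(index=False):
        system = str(row.code_system).strip().upper()
        if system in out:
            out[system].append(normalize_code(row.code))
    return out


def _matches_any(codes: Iterable[str], prefixes: Sequence[str]) -> bool:
    return any(code.startswith(p) for code in codes for p in prefixes)


def _category_present(codes: dict[str, list[str]], spec: Mapping) -> bool:
    return _matches_any(codes["ICD9"], spec.get("icd9_prefixes", ())) or _matches_any(
        codes["ICD10"], spec.get("icd10_prefixes", ())
    )


def flag_comorbidities(
    diagnoses: pd.DataFrame,
    category_codes: Mapping | None = None,
) -> dict[str, bool]:
    """Binary comorbidity flags for one patient's diagnosis rows.

    A flag is true iff any diagnosis code matches a category prefix.  Nested
    CKD stage flags are made consistent afterwards (stage 4 or 5 implies
    stages 3-5).
    """
    if category_codes is None:
        category_codes = default_comorbidity_categories()
    categories = category_codes["categories"]
    if not categories:
        raise ValueError("category config is empty")
    for name, spec in categories.items():
        if not spec.get("icd9_prefixes") and not spec.get("icd10_prefixes"):
            raise ValueError(f"category {name!r} has no code prefixes")
    codes = _codes_by_system(diagnoses)
    flags = {name: _category_present(codes, spec) for name, spec in categories.items()}
    for parent, children in category_codes.get("nested", {}).items():
        if parent in flags:
            flags[parent] = flags[parent] or any(flags.get(c, False) for c in children)
    return flags


def charlson_index(
    diagnoses: pd.DataFrame,
    charlson_map: CharlsonMap | None = None,
) -> int:
    """Charlson comorbidity index: weighted sum over present categories with
    hierarchy applied (e.g. metastatic disease supersedes any malignancy)."""
    if charlson_map is None:
        charlson_map = CharlsonMap.default()
    codes = _codes_by_system(diagnoses)
    present = {
        name for name, spec in charlson_map.categories.items() if _category_present(codes, spec)
    }
    for severe, mild in charlson_map.hierarchy:
        if severe in present:
            present.discard(mild)
    return sum(charlson_map.categories[name]["weight"] for name in present)


def select_closest_lab(
    series: Sequence[tuple[date, float]],
    index_date: date,
) -> float | None:
    """Value whose date minimises |date - index_date|; ties break toward the
    earlier date; None when the series is empty (absence is propagated)."""
    if not series:
        return None
    best = min(series, key=lambda dv: (abs((dv[0] - index_date).days), dv[0]))
    return best[1]


def summarize_utilization(
    encounters: pd.DataFrame,
    medications: pd.DataFrame,
    index_date: date,
    window: StudyWindow,
) -> tuple[int, dict[str, bool]]:
    """In-window hospitalization count plus post-index medication flags.

    A medication flag is true iff any dispense of the class falls in
    [index_date, window.end) — inclusive of the index date itself.
    """
    n_hosp = 0
    for row in encounters.itertuples(index=False):
        if bool(row.is_hospitalization) and date.fromisoformat(str(row.encounter_date)) in window:
            n_hosp += 1
    flags = {cls: False for cls in MEDICATION_CLASSES}
    for row in medications.itertuples(index=False):
        cls = str(row.drug_class)
        if cls not in flags:
            continue
        d = date.fromisoformat(str(row.dispense_date))
        if index_date <= d < window.end:
            flags[cls] = True
    return n_hosp, flags


def _lab_series(labs: pd.DataFrame, analyte: str) -> list[tuple[date, float]]:
    rows = labs[labs["analyte"] == analyte]
    return [(date.fromisoformat(str(r.date)), float(r.value)) for r in rows.itertuples(index=False)]


def derive_bmi(labs: pd.DataFrame, index_date: date) -> float | None:
    """BMI recomputed from closest height and weight when both exist, else
    the closest recorded BMI value."""
    height = select_closest_lab(_lab_series(labs, "height"), index_date)
    weight = select_closest_lab(_lab_series(labs, "weight"), index_date)
    if height and weight and height > 0:
        return round(weight / (height / 100.0) ** 2, 2)
    return select_closest_lab(_lab_series(labs, "bmi"), index_date)


CONTINUOUS_VARIABLES = ("bmi", "weight", "albumin", "prealbumin", "hba1c", "charlson_index", "hospitalizations")
BINARY_COMORBIDITY_ORDER = (
    "diabetes_with_complication",
    "diabetes_without_complication",
    "hypertension",
    "cardiovascular_disease",
    "peripheral_vascular_disease",
    "ckd_stages_3_5",
    "ckd_stage_4",
    "ckd_stage_5",
    "any_malignancy",
    "liver_disease",
    "depression",
    "aids",
    "neurologic_conditions",
    "fractures",
    "osteoporosis",
)


def _patients_matching(diagnoses: pd.DataFrame, icd9, icd10) -> pd.Index:
    """Patient ids with any diagnosis code matching the given prefixes."""
    if diagnoses.empty:
        return pd.Index([])
    system = diagnoses["code_system"].astype(str).str.strip().str.upper()
    code = diagnoses["code"].astype(str).str.strip().str.upper()
    mask = pd.Series(False, index=diagnoses.index)
    if icd9:
        mask |= (system == "ICD9") & code.str.startswith(tuple(icd9))
    if icd10:
        mask |= (system == "ICD10") & code.str.startswith(tuple(icd10))
    return pd.Index(diagnoses.loc[mask, "patient_id"].astype(str).unique())


def _closest_values(labs: pd.DataFrame, analyte: str, index_dates: pd.Series) -> pd.Series:
    """Per-patient lab value closest to the index date (ties -> earlier)."""
    sub = labs[labs["analyte"] == analyte]
    if sub.empty:
        return pd.Series(dtype=float)
    sub = sub.merge(index_dates.rename("index_date"), left_on="patient_id", right_index=True)
    lab_date = pd.to_datetime(sub["date"])
    gap = (lab_date - pd.to_datetime(sub["index_date"])).abs()
    sub = sub.assign(_gap=gap, _date=lab_date)
    sub = sub.sort_values(["patient_id", "_gap", "_date"], kind="stable")
    best = sub.groupby("patient_id").first()
    return best["value"].astype(float)


def build_variables(
    dataset,
    phenotypes: pd.DataFrame,
    window: StudyWindow,
    category_codes: Mapping | None = None,
    charlson_map: CharlsonMap | None = None,
) -> pd.DataFrame:
    """One row per patient with an index date: comorbidity flags, Charlson
    index (and the >2 indicator), index-anchored labs, hospitalization count
    and post-index medication flags.

    Vectorised equivalent of applying flag_comorbidities / charlson_index /
    select_closest_lab / summarize_utilization patient by patient.
    """
    if category_codes is None:
        category_codes = default_comorbidity_categories()
    if charlson_map is None:
        charlson_map = CharlsonMap.default()

    with_index = phenotypes[phenotypes["index_date"].astype(str) != ""]
    pids = with_index["patient_id"].astype(str)
    index_dates = pd.Series(
        pd.to_datetime(with_index["index_date"]).to_numpy(), index=pids.to_numpy()
    )
    out = pd.DataFrame({"patient_id": pids.to_numpy(), "index_date": with_index["index_date"].to_numpy()})
    out = out.set_index("patient_id")

    diagnoses = dataset.diagnoses
    for name in BINARY_COMORBIDITY_ORDER:
        spec = category_codes["categories"][name]
        hit = _patients_matching(diagnoses, spec.get("icd9_prefixes"), spec.get("icd10_prefixes"))
        out[name] = out.index.isin(hit)
    for parent, children in category_codes.get("nested", {}).items():
        if parent in out:
            for child in children:
                out[parent] = out[parent] | out[child]

    cat_flags = pd.DataFrame(index=out.index)
    for name, spec in charlson_map.categories.items():
        hit = _patients_matching(diagnoses, spec.get("icd9_prefixes"), spec.get("icd10_prefixes"))
        cat_flags[name] = cat_flags.index.isin(hit)
    for severe, mild in charlson_map.hierarchy:
        cat_flags[mild] = cat_flags[mild] & ~cat_flags[severe]
    weights = pd.Series({n: s["weight"] for n, s in charlson_map.categories.items()})
    out["charlson_index"] = (cat_flags * weights).sum(axis=1).astype(int)
    out["charlson_gt2"] = out["charlson_index"] > 2

    labs = dataset.labs
    height = _closest_values(labs, "height", index_dates)
    weight = _closest_values(labs, "weight", index_dates)
    recorded_bmi = _closest_values(labs, "bmi", index_dates)
    recomputed = (weight / (height / 100.0) ** 2).round(2)
    out["bmi"] = recomputed.reindex(out.index).fillna(recorded_bmi.reindex(out.index))
    out["weight"] = weight.reindex(out.index)
    for analyte in ("albumin", "prealbumin", "hba1c"):
        out[analyte] = _closest_values(labs, analyte, index_dates).reindex(out.index)

    enc = dataset.encounters
    if len(enc):
        enc_date = pd.to_datetime(enc["encounter_date"])
        in_window = (enc_date >= pd.Timestamp(window.start)) & (enc_date < pd.Timestamp(window.end))
        hosp = enc[in_window & enc["is_hospitalization"].astype(bool)]
        counts = hosp.groupby(hosp["patient_id"].astype(str)).size()
        out["hospitalizations"] = counts.reindex(out.index).fillna(0).astype(int)
    else:
        out["hospitalizations"] = 0

    meds = dataset.medications
    for cls in MEDICATION_CLASSES:
        out[f"med_{cls}"] = False
    if len(meds):
        sub = meds.merge(index_dates.rename("_idx"), left_on="patient_id", right_index=True)
        d = pd.to_datetime(sub["dispense_date"])
        post = (d >= sub["_idx"]) & (d < pd.Timestamp(window.end))
        sub = sub[post]
        for cls, grp in sub.groupby("drug_class"):
            col = f"med_{cls}"
            if col in out:
                out[col] = out.index.isin(grp["patient_id"].astype(str).unique())

    columns = (
        ["index_date"]
        + list(BINARY_COMORBIDITY_ORDER)
        + ["charlson_index", "charlson_gt2", "bmi", "weight", "albumin", "prealbumin", "hba1c", "hospitalizations"]
        + [f"med_{cls}" for cls in MEDICATION_CLASSES]
    )
    return out[columns].reset_index()
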