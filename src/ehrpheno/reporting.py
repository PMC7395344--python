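"""Result tables: the term/code cross-tabulation, the matched case-control
comparison, the coded-vs-text-only comparison, and per-condition subgroup
analyses.

Every number in a report is computed from the written intermediate tables
(mentions -> phenotypes -> pairs -> variables), so any cell is traceable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical_vars import BINARY_COMORBIDITY_ORDER, MEDICATION_CLASSES
from .nlp_engine import CONDITIONS
from .phenotyping import STATUS_CASE, STATUS_REJECTED
from . import stats as st

_ITEMS = [f"text_{c}" for c in CONDITIONS] + [f"code_{c}" for c in CONDITIONS]


@dataclass
class CrossTab:
    """Upper-triangular co-occurrence counts over the six items
    (text x 3 conditions, code x 3 conditions) among confirmed cases, plus
    derived overlap summaries.  Percentages use the total case n as the
    denominator."""

    matrix: pd.DataFrame
    total_cases: int
    derived: dict

    def to_json(self) -> dict:
        return {
            "total_cases": self.total_cases,
            "matrix": {
                r: {c: int(self.matrix.loc[r, c]) for c in self.matrix.columns}
                for r in self.matrix.index
            },
            "derived": self.derived,
        }


def cross_tab_terms_codes(case_items: Sequence[tuple[frozenset, frozenset]]) -> CrossTab:
    """Build the cross-tabulation from per-case (text conditions, code
    conditions) item sets.

    The diagonal holds per-item totals; off-diagonal (i, j) counts cases with
    both items.  Derived summaries include the disjoint multi-condition
    subsets and an inclusion-exclusion check for "more than one code".
    """
    n = len(case_items)
    item_index = {item: i for i, item in enumerate(_ITEMS)}
    counts = np.zeros((6, 6), dtype=int)
    n_multi = 0
    subsets = {"all_three": 0, "sarcopenia+cachexia": 0, "sarcopenia+frailty": 0, "cachexia+frailty": 0}
    any_text = all_text = no_text = any_code = all_code = no_code = 0
    more_than_one_code_direct = 0
    for text_set, code_set in case_items:
        idx = sorted(
            [item_index[f"text_{c}"] for c in text_set] + [item_index[f"code_{c}"] for c in code_set]
        )
        for i, r in enumerate(idx):
            for c in idx[i:]:
                counts[r, c] += 1
        conditions = frozenset(text_set) | frozenset(code_set)
        if len(conditions) >= 2:
            n_multi += 1
            if len(conditions) == 3:
                subsets["all_three"] += 1
            else:
                subsets["+".join(sorted(conditions, key=CONDITIONS.index))] += 1
        any_text += bool(text_set)
        all_text += len(text_set) == 3
        no_text += not text_set
        any_code += bool(code_set)
        all_code += len(code_set) == 3
        no_code += not code_set
        more_than_one_code_direct += len(code_set) >= 2

    matrix = pd.DataFrame(counts, index=_ITEMS, columns=_ITEMS)
    code_pair_sum = sum(
        int(matrix.loc[f"code_{c1}", f"code_{c2}"])
        for i, c1 in enumerate(CONDITIONS)
        for c2 in CONDITIONS[i + 1 :]
    )
    all_three_codes = all_code
    derived = {
        "any_text": any_text,
        "all_three_text": all_text,
        "no_text": no_text,
        "any_code": any_code,
        "all_three_codes": all_three_codes,
        "no_code": no_code,
        "n_multi_condition": n_multi,
        "multi_condition_subsets": subsets,
        "more_than_one_code_direct": more_than_one_code_direct,
        # inclusion-exclusion identity: sum of pairwise co-occurrences minus
        # twice the triple count equals the direct >=2-codes count
        "more_than_one_code_incl_excl": code_pair_sum - 2 * all_three_codes,
        "pct_any_code": round(100.0 * any_code / n, 1) if n else float("nan"),
        "pct_no_code": round(100.0 * no_code / n, 1) if n else float("nan"),
        "pct_multi_condition": round(100.0 * n_multi / n, 1) if n else float("nan"),
    }
    return CrossTab(matrix=matrix, total_cases=n, derived=derived)


def case_items_from_occurrences(phenotypes: pd.DataFrame, occurrences) -> list[tuple[frozenset, frozenset]]:
    """Per confirmed case, the sets of conditions seen positively as text and
    as codes."""
    case_ids = set(phenotypes.loc[phenotypes["status"] == STATUS_CASE, "patient_id"].astype(str))
    text: dict[str, set] = {pid: set() for pid in case_ids}
    code: dict[str, set] = {pid: set() for pid in case_ids}
    for occ in occurrences:
        if occ.patient_id not in case_ids or occ.label != "positive":
            continue
        (text if occ.source == "text" else code)[occ.patient_id].add(occ.condition)
    return [(frozenset(text[pid]), frozenset(code[pid])) for pid in sorted(case_ids)]


def phenotype_summary(phenotypes: pd.DataFrame, occurrences) -> dict:
    """Cohort-level phenotype arithmetic: confirmation rate, detection-source
    shares, and per-condition patient-level positive-use rates."""
    status = phenotypes["status"]
    n_cases = int((status == STATUS_CASE).sum())
    n_rejected = int((status == STATUS_REJECTED).sum())
    n_presumptive = n_cases + n_rejected
    source = phenotypes.loc[status == STATUS_CASE, "detection_source"]
    n_text_only = int((source == "text_only").sum())
    n_with_code = int(source.isin(["code_only", "code_and_text"]).sum())

    # patient-level positive term use per condition: among patients with any
    # text occurrence of the condition, the share with a positive one
    presumptive_ids = set(phenotypes.loc[status.isin([STATUS_CASE, STATUS_REJECTED]), "patient_id"].astype(str))
    term_users: dict[str, set] = {c: set() for c in CONDITIONS}
    positive_users: dict[str, set] = {c: set() for c in CONDITIONS}
    for occ in occurrences:
        if occ.source != "text" or occ.patient_id not in presumptive_ids:
            continue
        term_users[occ.condition].add(occ.patient_id)
        if occ.label == "positive":
            positive_users[occ.condition].add(occ.patient_id)
    positive_use = {
        c: {
            "n_positive": len(positive_users[c]),
            "n_with_term": len(term_users[c]),
            "rate_pct": round(100.0 * len(positive_users[c]) / len(term_users[c]), 1)
            if term_users[c]
            else float("nan"),
        }
        for c in CONDITIONS
    }
    return {
        "n_presumptive": n_presumptive,
        "n_confirmed": n_cases,
        "n_rejected": n_rejected,
        "confirmation_rate_pct": round(100.0 * n_cases / n_presumptive, 1) if n_presumptive else float("nan"),
        "rejected_rate_pct": round(100.0 * n_rejected / n_presumptive, 1) if n_presumptive else float("nan"),
        "n_text_only": n_text_only,
        "text_only_pct": round(100.0 * n_text_only / n_cases, 1) if n_cases else float("nan"),
        "n_with_code": n_with_code,
        "with_code_pct": round(100.0 * n_with_code / n_cases, 1) if n_cases else float("nan"),
        "positive_use": positive_use,
    }


@dataclass
class ReportRow:
    variable: str
    kind: str  # continuous | binary
    case_summary: str
    control_summary: str
    result: st.TestResult | None
    n_used: int
    flags: list[str] = field(default_factory=list)


@dataclass
class AnalysisReport:
    title: str
    header: dict
    rows: list[ReportRow]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            r = row.result
            records.append(
                {
                    "variable": row.variable,
                    "kind": row.kind,
                    "cases": row.case_summary,
                    "controls": row.control_summary,
                    "estimate": r.estimate if r else None,
                    "ci_low": r.ci_low if r else None,
                    "ci_high": r.ci_high if r else None,
                    "p_value": r.p_value if r else None,
                    "test": r.method if r else "",
                    "n_used": row.n_used,
                    "flags": ";".join(row.flags + (r.flags if r else [])),
                }
            )
        return pd.DataFrame(
            records,
            columns=["variable", "kind", "cases", "controls", "estimate", "ci_low", "ci_high", "p_value", "test", "n_used", "flags"],
        )

    def to_json(self) -> dict:
        return {
            "title": self.title,
            "header": self.header,
            "rows": [
                {
                    "variable": row.variable,
                    "kind": row.kind,
                    "cases": row.case_summary,
                    "controls": row.control_summary,
                    "result": row.result.to_dict() if row.result else None,
                    "n_used": row.n_used,
                    "flags": row.flags,
                }
                for row in self.rows
            ],
        }


def _median_iqr(values: np.ndarray) -> str:
    if values.size == 0:
        return "NA"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def _count_pct(flags: np.ndarray) -> str:
    n = flags.size
    k = int(flags.sum())
    return f"{k} ({100.0 * k / n:.1f}%)" if n else "NA"


CONTINUOUS_ROWS = ("bmi", "weight", "albumin", "prealbumin", "hba1c", "charlson_index", "hospitalizations")
BINARY_ROWS = tuple(BINARY_COMORBIDITY_ORDER) + ("charlson_gt2",) + tuple(f"med_{c}" for c in MEDICATION_CLASSES)


def _cohort_header(pairs: pd.DataFrame, window_start_year: int) -> dict:
    n = len(pairs)
    if n == 0:
        return {"n_pairs": 0}
    age = window_start_year - pairs["birth_year"].to_numpy()
    q1, med, q3 = np.percentile(age, [25, 50, 75])
    header = {
        "n_pairs": n,
        "age_median": float(med),
        "age_q1": float(q1),
        "age_q3": float(q3),
        "female_n": int((pairs["sex"] == "female").sum()),
        "female_pct": round(100.0 * (pairs["sex"] == "female").mean(), 1),
    }
    for race in ("black", "white", "other"):
        header[f"race_{race}_n"] = int((pairs["race"] == race).sum())
    # matched variables are identical across arms by construction
    header["matched_demographics_identical"] = True
    return header


def case_control_table(
    pairs: pd.DataFrame,
    variables: pd.DataFrame,
    title: str = "case_control",
    window_start_year: int = 2016,
) -> AnalysisReport:
    """Matched comparison: continuous rows get median (Q1, Q3) per arm and a
    signed-rank p; binary rows get n (%) per arm and the matched-pair
    conditional OR with 95% CI and McNemar p.  Pairs missing a value are
    dropped per variable (pairwise-complete)."""
    vars_by_pid = variables.set_index("patient_id")
    case_vars = vars_by_pid.reindex(pairs["case_id"].astype(str))
    ctrl_vars = vars_by_pid.reindex(pairs["control_id"].astype(str))
    rows: list[ReportRow] = []
    for var in CONTINUOUS_ROWS:
        a = pd.to_numeric(case_vars[var], errors="coerce").to_numpy(dtype=float)
        b = pd.to_numeric(ctrl_vars[var], errors="coerce").to_numpy(dtype=float)
        complete = ~(np.isnan(a) | np.isnan(b))
        flags = []
        if complete.sum() == 0:
            rows.append(ReportRow(var, "continuous", "NA", "NA", None, 0, ["no_complete_pairs"]))
            continue
        result = st.signed_rank_test(a[complete], b[complete])
        rows.append(
            ReportRow(
                var,
                "continuous",
                _median_iqr(a[~np.isnan(a)]),
                _median_iqr(b[~np.isnan(b)]),
                result,
                int(complete.sum()),
                flags,
            )
        )
    for var in BINARY_ROWS:
        a = case_vars[var].fillna(False).astype(bool).to_numpy()
        b = ctrl_vars[var].fillna(False).astype(bool).to_numpy()
        counts = st.PairExposureCounts.from_pairs(a, b)
        result = st.matched_pairs_or(counts)
        rows.append(ReportRow(var, "binary", _count_pct(a), _count_pct(b), result, counts.n_pairs))
    return AnalysisReport(title=title, header=_cohort_header(pairs, window_start_year), rows=rows)


def coded_vs_text_table(
    phenotypes: pd.DataFrame,
    variables: pd.DataFrame,
    title: str = "coded_vs_text",
    window_start_year: int = 2016,
    patients: pd.DataFrame | None = None,
) -> AnalysisReport:
    """Unpaired comparison of cases with phenotype ICD codes versus cases
    detected by text terms only (rank-sum / chi-square or Fisher)."""
    cases = phenotypes[phenotypes["status"] == STATUS_CASE].copy()
    coded_ids = cases.loc[cases["detection_source"].isin(["code_only", "code_and_text"]), "patient_id"]
    text_ids = cases.loc[cases["detection_source"] == "text_only", "patient_id"]
    if len(coded_ids) == 0:
        raise ValueError("stratum 'with ICD codes' is empty")
    if len(text_ids) == 0:
        raise ValueError("stratum 'text terms only' is empty")
    vars_by_pid = variables.set_index("patient_id")
    coded = vars_by_pid.reindex(coded_ids.astype(str))
    text = vars_by_pid.reindex(text_ids.astype(str))
    rows: list[ReportRow] = []
    if patients is not None:
        by_pid = patients.set_index("patient_id")["birth_year"]
        age_coded = (window_start_year - by_pid.reindex(coded_ids.astype(str))).dropna().to_numpy(dtype=float)
        age_text = (window_start_year - by_pid.reindex(text_ids.astype(str))).dropna().to_numpy(dtype=float)
        result = st.rank_sum_test(age_coded, age_text)
        rows.append(
            ReportRow("age", "continuous", _median_iqr(age_coded), _median_iqr(age_text), result,
                      int(age_coded.size + age_text.size))
        )
    for var in CONTINUOUS_ROWS:
        a = pd.to_numeric(coded[var], errors="coerce").dropna().to_numpy(dtype=float)
        b = pd.to_numeric(text[var], errors="coerce").dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            rows.append(ReportRow(var, "continuous", "NA", "NA", None, 0, ["empty_after_missing"]))
            continue
        result = st.rank_sum_test(a, b)
        rows.append(ReportRow(var, "continuous", _median_iqr(a), _median_iqr(b), result, int(a.size + b.size)))
    for var in BINARY_ROWS:
        a = coded[var].fillna(False).astype(bool).to_numpy()
        b = text[var].fillna(False).astype(bool).to_numpy()
        table = [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
        result = st.categorical_test(table)
        rows.append(ReportRow(var, "binary", _count_pct(a), _count_pct(b), result, int(a.size + b.size)))
    header = {"n_coded": int(len(coded_ids)), "n_text_only": int(len(text_ids))}
    return AnalysisReport(title=title, header=header, rows=rows)


def subgroup_tables(
    phenotypes: pd.DataFrame,
    pairs: pd.DataFrame,
    variables: pd.DataFrame,
    window_start_year: int = 2016,
) -> dict[str, AnalysisReport]:
    """Per-condition analyses restricted to cases whose condition set is
    exactly that single condition, each against its own matched controls."""
    cases = phenotypes[phenotypes["status"] == STATUS_CASE]
    singleton = cases.set_index("patient_id")["conditions"]
    out: dict[str, AnalysisReport] = {}
    for condition in CONDITIONS:
        ids = set(singleton[singleton == condition].index.astype(str))
        sub_pairs = pairs[pairs["case_id"].astype(str).isin(ids)].reset_index(drop=True)
        out[condition] = case_control_table(
            sub_pairs, variables, title=f"subgroup_{condition}", window_start_year=window_start_year
        )
    return out


def write_report(report: AnalysisReport, basename, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    report.to_frame().to_csv(outdir / f"{basename}.tsv", sep="\t", index=False)
    (outdir / f"{basename}.json").write_text(json.dumps(report.to_json(), indent=1, sort_keys=True))
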