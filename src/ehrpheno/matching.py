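"""1:1 exact matching of controls to cases on (birth year, sex, race).

Within each exact-key stratum, min(#cases, #controls) pairs are formed
without replacement; control selection within a stratum is uniform at random
under a recorded seed, so results are reproducible.  For exact-key matching,
greedy per-stratum assignment attains the maximum bipartite matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female")
RACES = ("black", "white", "other")


class MatchKey(NamedTuple):
    birth_year: int
    sex: str
    race: str


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    key: MatchKey


@dataclass
class MatchResult:
    pairs: list[MatchedPair]
    unmatched_cases: list[str]
    stratum_counts: dict[MatchKey, tuple[int, int, int]]  # (n_cases, n_pool, n_pairs)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        pairs = pd.DataFrame(
            [
                {
                    "pair_id": i,
                    "case_id": p.case_id,
                    "control_id": p.control_id,
                    "birth_year": p.key.birth_year,
                    "sex": p.key.sex,
                    "race": p.key.race,
                }
                for i, p in enumerate(self.pairs)
            ],
            columns=["pair_id", "case_id", "control_id", "birth_year", "sex", "race"],
        )
        unmatched = pd.DataFrame({"case_id": self.unmatched_cases}, columns=["case_id"])
        return pairs, unmatched


def _validate_key(key: MatchKey) -> MatchKey:
    key = MatchKey(int(key[0]), str(key[1]), str(key[2]))
    if key.sex not in SEXES:
        raise ValueError(f"sex {key.sex!r} not in {SEXES}")
    if key.race not in RACES:
        raise ValueError(f"race {key.race!r} not in {RACES}")
    return key


def match_controls(
    cases: Sequence[tuple[str, MatchKey]],
    pool: Sequence[tuple[str, MatchKey]],
    rng_seed: int = 0,
) -> MatchResult:
    """Match each case to one unused control with an identical key.

    Deterministic given the seed; surplus cases in a stratum are reported
    unmatched rather than matched loosely.
    """
    ids = [pid for pid, _ in cases] + [pid for pid, _ in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id across cases and pool")
    rng = np.random.default_rng(rng_seed)

    case_strata: dict[MatchKey, list[str]] = {}
    for pid, key in cases:
        case_strata.setdefault(_validate_key(key), []).append(str(pid))
    pool_strata: dict[MatchKey, list[str]] = {}
    for pid, key in pool:
        pool_strata.setdefault(_validate_key(key), []).append(str(pid))

    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    counts: dict[MatchKey, tuple[int, int, int]] = {}
    for key in sorted(case_strata):
        stratum_cases = sorted(case_strata[key])
        stratum_pool = sorted(pool_strata.get(key, []))
        order = rng.permutation(len(stratum_pool))
        k = min(len(stratum_cases), len(stratum_pool))
        for i in range(k):
            pairs.append(MatchedPair(stratum_cases[i], stratum_pool[order[i]], key))
        unmatched.extend(stratum_cases[k:])
        counts[key] = (len(stratum_cases), len(stratum_pool), k)
    return MatchResult(pairs=pairs, unmatched_cases=unmatched, stratum_counts=counts)


@dataclass
class MatchAudit:
    violations: list[str]
    demographics: pd.DataFrame

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_matching(
    result: MatchResult,
    cases: Sequence[tuple[str, MatchKey]],
    pool: Sequence[tuple[str, MatchKey]],
) -> MatchAudit:
    """Audit a match result: key equality per pair, no control reuse, and
    per-stratum pair counts equal to min(#cases, #controls).

    The demographic table summarises the matched set per arm; matched
    variables are identical between arms by construction.
    """
    case_keys = {str(pid): _validate_key(k) for pid, k in cases}
    pool_keys = {str(pid): _validate_key(k) for pid, k in pool}
    violations: list[str] = []

    seen_controls: set[str] = set()
    for p in result.pairs:
        if p.case_id not in case_keys:
            violations.append(f"unknown case {p.case_id}")
            continue
        if p.control_id not in pool_keys:
            violations.append(f"unknown control {p.control_id}")
            continue
        if p.control_id in seen_controls:
            violations.append(f"control reuse: {p.control_id}")
        seen_controls.add(p.control_id)
        if case_keys[p.case_id] != pool_keys[p.control_id] or case_keys[p.case_id] != p.key:
            violations.append(f"key mismatch in pair ({p.case_id}, {p.control_id})")

    if len(result.pairs) + len(result.unmatched_cases) != len(cases):
        violations.append("pairs + unmatched does not partition the cases")

    strata_cases: dict[MatchKey, int] = {}
    for key in case_keys.values():
        strata_cases[key] = strata_cases.get(key, 0) + 1
    strata_pool: dict[MatchKey, int] = {}
    for key in pool_keys.values():
        strata_pool[key] = strata_pool.get(key, 0) + 1
    strata_pairs: dict[MatchKey, int] = {}
    for p in result.pairs:
        strata_pairs[p.key] = strata_pairs.get(p.key, 0) + 1
    for key, n_cases in strata_cases.items():
        expected = min(n_cases, strata_pool.get(key, 0))
        if strata_pairs.get(key, 0) != expected:
            violations.append(
                f"stratum {key}: {strata_pairs.get(key, 0)} pairs, expected {expected}"
            )

    rows = []
    for arm, getter in (("cases", lambda p: p.case_id), ("controls", lambda p: p.control_id)):
        keys = [p.key for p in result.pairs]
        n = len(keys)
        row = {"arm": arm, "n": n}
        row["female_n"] = sum(1 for k in keys if k.sex == "female")
        for race in RACES:
            row[f"race_{race}_n"] = sum(1 for k in keys if k.race == race)
        row["birth_year_median"] = float(np.median([k.birth_year for k in keys])) if n else float("nan")
        rows.append(row)
    demographics = pd.DataFrame(rows)
    return MatchAudit(violations=violations, demographics=demographics)
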