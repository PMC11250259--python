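"""Case-level processing: deduplication, cohort selection, derived fields.

FAERS cases are re-reported across quarters under the same CASEID with new
PRIMARYID versions.  The FDA deduplication rule keeps, per CASEID, the record
with the latest FDA_DT, breaking ties by the largest PRIMARYID.  Cohort
selection is keyword-substring matching on normalized drug name / active
ingredient restricted to a role code (typically PS, primary suspect).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .dates import parse_faers_date, days_between

AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}

WEIGHT_FACTORS = {"KG": 1.0, "LBS": 0.45359237, "GMS": 0.001}

OCCUPATION_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "HP": "Health professional",
    "RN": "Registered nurse",
}

# half-open bins: list of (lower, upper, label); upper=None means unbounded
AGE_DESCRIPTIVE_BINS = [
    (0.0, 18.0, "≤17"),
    (18.0, 65.0, "18~64"),
    (65.0, 86.0, "65~85"),
    (86.0, None, "≥86"),
]
AGE_STRATA_BINS = [
    (0.0, 18.0, "<18"),
    (18.0, 65.0, "18–65"),
    (65.0, None, ">65"),
]
WEIGHT_STRATA_BINS = [
    (0.0, 50.0, "<50 kg"),
    (50.0, 100.0, "50–100 kg"),
    (100.0, None, ">100 kg"),
]
ONSET_BINS = [
    (0, 8, "0–7"),
    (8, 29, "8–28"),
    (29, 61, "29–60"),
    (61, None, "≥60"),
]

_PUNCT = re.compile(r"[^A-Z0-9 ]+")


def normalize_drug_text(text: str) -> str:
    """Uppercase, strip punctuation, collapse whitespace (matching only)."""
    return " ".join(_PUNCT.sub(" ", str(text).upper()).split())


def deduplicate(demo: pd.DataFrame) -> Set[str]:
    """Return the kept PRIMARYID set: per CASEID, latest FDA_DT, then largest
    PRIMARYID.  Idempotent and order-independent (pure set semantics)."""
    if demo.empty:
        return set()
    frame = demo[["primaryid", "caseid", "fda_dt"]].copy()
    # PRIMARYIDs compare numerically when possible, else lexicographically
    pid_num = pd.to_numeric(frame["primaryid"], errors="coerce")
    if pid_num.notna().all():
        frame["_pid_key"] = pid_num
    else:
        frame["_pid_key"] = frame["primaryid"]
    frame = frame.sort_values(["caseid", "fda_dt", "_pid_key"], kind="mergesort")
    kept = frame.groupby("caseid", sort=False).tail(1)
    return set(kept["primaryid"])


def select_target_reports(
    drug: pd.DataFrame, keywords: Sequence[str], role: str = "PS"
) -> Set[str]:
    """PRIMARYIDs having >=1 drug row with the given role whose normalized
    drugname or active ingredient contains a normalized keyword."""
    if not keywords:
        raise ValueError("keyword list must be nonempty")
    normed = [normalize_drug_text(k) for k in keywords]
    if any(not k for k in normed):
        raise ValueError("keywords must contain matchable text")
    sub = drug[drug["role_cod"] == role.upper()]
    if sub.empty:
        return set()
    name = sub["drugname"].map(normalize_drug_text)
    ai = sub.get("prod_ai", pd.Series("", index=sub.index)).map(normalize_drug_text)
    hit = pd.Series(False, index=sub.index)
    for kw in normed:
        hit |= name.str.contains(kw, regex=False) | ai.str.contains(kw, regex=False)
    return set(sub.loc[hit, "primaryid"])


def normalize_age(value, unit_code: Optional[str], default_unit: str = "YR"):
    """Convert an (age value, unit code) pair to years.

    Returns ``(years, flagged)`` where ``flagged`` marks a defaulted missing
    unit.  Negative or unparseable values return ``(None, False)``.
    """
    years = _convert(value, unit_code, AGE_FACTORS, default_unit)
    if years is None:
        return None, False
    val, defaulted = years
    if val < 0:
        return None, False
    return val, defaulted


def normalize_weight(value, unit_code: Optional[str], default_unit: str = "KG"):
    """Convert (weight value, unit code) to kilograms; nonpositive -> None."""
    kg = _convert(value, unit_code, WEIGHT_FACTORS, default_unit)
    if kg is None:
        return None, False
    val, defaulted = kg
    if val <= 0:
        return None, False
    return val, defaulted


def _convert(value, unit_code, factors, default_unit):
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if np.isnan(v):
        return None
    unit = (unit_code or "").strip().upper()
    if not unit:
        return v * factors[default_unit], True
    if unit not in factors:
        return None
    return v * factors[unit], False


def onset_days(event_dt, therapy_start_dt) -> Optional[int]:
    """Days from therapy start to event; requires day precision on both,
    negative differences are treated as unknown."""
    d = days_between(parse_faers_date(event_dt), parse_faers_date(therapy_start_dt))
    if d is None or d < 0:
        return None
    return d


def assign_bin(value, bins) -> Optional[str]:
    """Map a value into its half-open [lower, upper) bin label; None for
    missing values or values below every bin."""
    if value is None:
        return None
    try:
        if np.isnan(value):
            return None
    except TypeError:
        pass
    for lower, upper, label in bins:
        if value >= lower and (upper is None or value < upper):
            return label
    return None


def occupation_label(code: Optional[str]) -> str:
    code = (code or "").strip().upper()
    return OCCUPATION_LABELS.get(code, "Missing")


def build_case_table(
    demo: pd.DataFrame,
    kept: Set[str],
    drug: Optional[pd.DataFrame] = None,
    ther: Optional[pd.DataFrame] = None,
    target_ids: Optional[Set[str]] = None,
    keywords: Optional[Sequence[str]] = None,
    role: str = "PS",
) -> pd.DataFrame:
    """Build the per-report derived table for the kept PRIMARYIDs.

    Columns: primaryid, caseid, fda_dt, year, sex, age_years, weight_kg,
    country, occupation, onset_days.  Onset is computed only for reports in
    ``target_ids`` (the cohort), from the target drug's earliest day-precise
    therapy start date.
    """
    frame = demo[demo["primaryid"].isin(kept)].copy()
    ages = [normalize_age(v, u)[0] for v, u in zip(frame["age"], frame["age_cod"])]
    weights = [normalize_weight(v, u)[0] for v, u in zip(frame["wt"], frame["wt_cod"])]
    out = pd.DataFrame(
        {
            "primaryid": frame["primaryid"].to_numpy(),
            "caseid": frame["caseid"].to_numpy(),
            "fda_dt": frame["fda_dt"].to_numpy(),
            "year": (frame["fda_dt"] // 10000).to_numpy(),
            "sex": frame["sex"].replace("", "UNK").to_numpy(),
            "age_years": np.array(ages, dtype=float),
            "weight_kg": np.array(weights, dtype=float),
            "country": frame["reporter_country"].to_numpy(),
            "occupation": frame["occp_cod"].map(occupation_label).to_numpy(),
            "event_dt": frame["event_dt"].to_numpy(),
        }
    )
    out["onset_days"] = np.nan
    if target_ids and drug is not None and ther is not None and keywords:
        starts = _target_therapy_start(drug, ther, target_ids, keywords, role)
        merged = out["primaryid"].map(starts)
        onset = [
            onset_days(ev, st) if pid in target_ids and st is not None else None
            for pid, ev, st in zip(out["primaryid"], out["event_dt"], merged)
        ]
        out["onset_days"] = np.array(
            [np.nan if d is None else float(d) for d in onset]
        )
    return out


def _target_therapy_start(drug, ther, target_ids, keywords, role):
    """Earliest day-precise start_dt among the target drug's therapy rows,
    per PRIMARYID."""
    normed = [normalize_drug_text(k) for k in keywords]
    sub = drug[drug["primaryid"].isin(target_ids) & (drug["role_cod"] == role.upper())]
    name = sub["drugname"].map(normalize_drug_text)
    ai = sub.get("prod_ai", pd.Series("", index=sub.index)).map(normalize_drug_text)
    hit = pd.Series(False, index=sub.index)
    for kw in normed:
        hit |= name.str.contains(kw, regex=False) | ai.str.contains(kw, regex=False)
    target_rows = sub[hit][["primaryid", "drug_seq"]]
    th = ther.merge(
        target_rows,
        left_on=["primaryid", "dsg_drug_seq"],
        right_on=["primaryid", "drug_seq"],
    )
    starts = {}
    for pid, raw in zip(th["primaryid"], th["start_dt"]):
        d = parse_faers_date(raw)
        if d is None or d.precision != "day":
            continue
        cur = starts.get(pid)
        if cur is None or d.as_date() < cur[0]:
            starts[pid] = (d.as_date(), raw)
    return {pid: raw for pid, (_, raw) in starts.items()}
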