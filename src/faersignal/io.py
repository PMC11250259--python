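"""Reading FAERS-style quarterly ASCII bundles.

Each quarterly bundle is a set of "$"-delimited text files (DEMO, DRUG, REAC,
OUTC, THER) with a single header line.  FAERS changed its schema mid-history:
early quarters key records by ISR/CASE, later ones by PRIMARYID/CASEID.  Both
dialects are handled through named *schema profiles* that map source column
names onto one canonical internal model (``primaryid``/``caseid``).

Parsing is strictly accounted: every input line either becomes a record or is
counted as skipped; ``records_in == records_parsed + records_skipped`` always
holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import pandas as pd

from .dates import parse_faers_date

logger = logging.getLogger(__name__)

FILE_KINDS = ("demo", "drug", "reac", "outc", "ther")

#: canonical columns per file kind (order is the internal contract)
CANONICAL_COLUMNS: Dict[str, tuple] = {
    "demo": (
        "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod",
        "wt", "wt_cod", "reporter_country", "occp_cod",
    ),
    "drug": ("primaryid", "drug_seq", "drugname", "prod_ai", "role_cod"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
}

#: source-column -> canonical-field maps, keyed by era profile then file kind
SCHEMA_PROFILES: Dict[str, Dict[str, Dict[str, str]]] = {
    # PRIMARYID era (2012Q4 onward)
    "current": {
        "demo": {
            "PRIMARYID": "primaryid", "CASEID": "caseid", "FDA_DT": "fda_dt",
            "EVENT_DT": "event_dt", "SEX": "sex", "GNDR_COD": "sex",
            "AGE": "age", "AGE_COD": "age_cod", "WT": "wt", "WT_COD": "wt_cod",
            "REPORTER_COUNTRY": "reporter_country", "OCCP_COD": "occp_cod",
        },
        "drug": {
            "PRIMARYID": "primaryid", "DRUG_SEQ": "drug_seq",
            "DRUGNAME": "drugname", "PROD_AI": "prod_ai", "ROLE_COD": "role_cod",
        },
        "reac": {"PRIMARYID": "primaryid", "PT": "pt"},
        "outc": {"PRIMARYID": "primaryid", "OUTC_COD": "outc_cod"},
        "ther": {
            "PRIMARYID": "primaryid", "DSG_DRUG_SEQ": "dsg_drug_seq",
            "START_DT": "start_dt",
        },
    },
    # ISR era (pre-2012Q4): records keyed by ISR, cases by CASE
    "legacy": {
        "demo": {
            "ISR": "primaryid", "CASE": "caseid", "FDA_DT": "fda_dt",
            "EVENT_DT": "event_dt", "GNDR_COD": "sex", "AGE": "age",
            "AGE_COD": "age_cod", "WT": "wt", "WT_COD": "wt_cod",
            "REPORTER_COUNTRY": "reporter_country", "OCCP_COD": "occp_cod",
        },
        "drug": {
            "ISR": "primaryid", "DRUG_SEQ": "drug_seq",
            "DRUGNAME": "drugname", "ROLE_COD": "role_cod",
        },
        "reac": {"ISR": "primaryid", "PT": "pt"},
        "outc": {"ISR": "primaryid", "OUTC_COD": "outc_cod"},
        "ther": {
            "ISR": "primaryid", "DRUG_SEQ": "dsg_drug_seq", "START_DT": "start_dt",
        },
    },
}

#: canonical fields that must be present after mapping
MANDATORY: Dict[str, tuple] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "start_dt"),
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization - initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention",
    "OT": "Other serious",
}


class SchemaError(ValueError):
    """A bundle file is missing a mandatory column."""


@dataclass
class RawTables:
    """One quarter's parsed file set, keyed by PRIMARYID."""

    quarter: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    skipped: Dict[str, int] = field(default_factory=dict)

    def orphan_counts(self) -> Dict[str, int]:
        """Records in non-DEMO tables whose PRIMARYID is absent from DEMO."""
        known = set(self.demo["primaryid"])
        return {
            kind: int((~getattr(self, kind)["primaryid"].isin(known)).sum())
            for kind in ("drug", "reac", "outc", "ther")
        }


def _normalize_text(s: str) -> str:
    return " ".join(s.split())


def read_table(path: str | Path, kind: str, profile: str = "current"):
    """Parse one "$"-delimited file into a canonical DataFrame.

    Returns ``(frame, n_skipped)``.  Lines whose field count disagrees with
    the header are skipped and counted, never silently dropped.
    """
    if kind not in FILE_KINDS:
        raise ValueError(f"unknown file kind {kind!r}")
    colmap = SCHEMA_PROFILES[profile][kind]
    with open(path, encoding="utf-8", errors="replace") as fh:
        header = fh.readline().rstrip("\r\n")
        source_cols = [c.strip().upper() for c in header.split("$")]
        canonical = [colmap.get(c) for c in source_cols]
        present = {c for c in canonical if c is not None}
        missing = [m for m in MANDATORY[kind] if m not in present]
        if missing:
            raise SchemaError(
                f"{path}: {kind.upper()} file lacks mandatory column(s) "
                f"{missing} under profile {profile!r}"
            )
        n_fields = len(source_cols)
        rows = []
        n_skipped = 0
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("$")
            if len(parts) != n_fields:
                n_skipped += 1
                continue
            rows.append(parts)
    frame = pd.DataFrame(rows, columns=canonical, dtype=str)
    # drop unmapped source columns, add absent canonical ones as empty
    frame = frame.loc[:, [c for c in frame.columns if c is not None]]
    for col in CANONICAL_COLUMNS[kind]:
        if col not in frame.columns:
            frame[col] = ""
    frame = frame[list(CANONICAL_COLUMNS[kind])]
    frame, n_bad = _postprocess(frame, kind)
    n_skipped += n_bad
    if n_skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, n_skipped)
    return frame.reset_index(drop=True), n_skipped


def _postprocess(frame: pd.DataFrame, kind: str):
    """Type/normalize canonical columns; rows failing hard invariants are
    dropped and counted."""
    n_bad = 0
    for col in frame.columns:
        frame[col] = frame[col].str.strip()
    if kind == "demo":
        ok = frame["fda_dt"].map(
            lambda s: (d := parse_faers_date(s)) is not None and d.precision == "day"
        )
        ok &= frame["primaryid"].str.len() > 0
        ok &= frame["caseid"].str.len() > 0
        n_bad = int((~ok).sum())
        frame = frame[ok].copy()
        frame["fda_dt"] = frame["fda_dt"].astype("int64")
        frame["sex"] = frame["sex"].str.upper().where(
            frame["sex"].str.upper().isin(["F", "M"]) | (frame["sex"] == ""), "UNK"
        )
    elif kind == "drug":
        frame["role_cod"] = frame["role_cod"].str.upper()
        frame["drugname"] = frame["drugname"].map(_normalize_text)
        frame["prod_ai"] = frame["prod_ai"].map(_normalize_text)
    elif kind == "reac":
        frame["pt"] = frame["pt"].map(_normalize_text)
        ok = frame["pt"].str.len() > 0
        n_bad = int((~ok).sum())
        frame = frame[ok].copy()
    elif kind == "outc":
        frame["outc_cod"] = frame["outc_cod"].str.upper()
    return frame, n_bad


def _default_paths(directory: Path, quarter: str) -> Dict[str, Path]:
    """Locate DEMO<yy>Q<q>.txt-style files for a quarter label like 2023Q3."""
    year, q = quarter.split("Q")
    stem = f"{year[2:]}Q{q}"
    paths = {}
    for kind in FILE_KINDS:
        candidates = [
            directory / f"{kind.upper()}{stem}.txt",
            directory / f"{kind.upper()}{stem}.TXT",
        ]
        found = next((p for p in candidates if p.exists()), None)
        if found is None:
            raise FileNotFoundError(
                f"no {kind.upper()} file for quarter {quarter} in {directory}"
            )
        paths[kind] = found
    return paths


def read_quarter(
    source: str | Path | Mapping[str, str | Path],
    quarter: str,
    profile: str = "current",
) -> RawTables:
    """Read one quarter's bundle into :class:`RawTables`.

    ``source`` is either a directory holding files named like ``DEMO23Q3.txt``
    or an explicit ``{kind: path}`` mapping.
    """
    if isinstance(source, Mapping):
        paths = {k: Path(v) for k, v in source.items()}
    else:
        paths = _default_paths(Path(source), quarter)
    frames: Dict[str, pd.DataFrame] = {}
    skipped: Dict[str, int] = {}
    for kind in FILE_KINDS:
        frames[kind], skipped[kind] = read_table(paths[kind], kind, profile)
    return RawTables(quarter=quarter, skipped=skipped, **frames)
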