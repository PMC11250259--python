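"""Synthetic FAERS-style bundle generator with planted signals.

The generator emulates the statistical structure of spontaneous-report data
that the pipeline depends on: many reports per case across quarters
(duplicates), multiple drugs per report with role codes (exactly one primary
suspect), multiple preferred terms per report, demographic fields carrying
FAERS unit codes with heavy missingness, and drug-event pair counts that are
multinomial around a background event distribution multiplied by a planted
relative risk for chosen (drug, PT) pairs.

Event sampling per report draws k PTs *without replacement* with weights
equal to the background event probabilities times the relative-risk
multiplier of the report's primary-suspect drug, renormalized — so a report
never lists the same PT twice, matching the (report, term) counting unit
downstream.

Everything is driven by a single integer seed; identical configurations
produce byte-identical bundles.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .io import RawTables, CANONICAL_COLUMNS

_SOURCE_HEADERS = {
    "demo": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
             "AGE_COD", "WT", "WT_COD", "REPORTER_COUNTRY", "OCCP_COD"],
    "drug": ["PRIMARYID", "DRUG_SEQ", "DRUGNAME", "PROD_AI", "ROLE_COD"],
    "reac": ["PRIMARYID", "PT"],
    "outc": ["PRIMARYID", "OUTC_COD"],
    "ther": ["PRIMARYID", "DSG_DRUG_SEQ", "START_DT"],
}

COUNTRIES = ["US", "JP", "GB", "FR", "CN"]
OCCUPATIONS = ["MD", "PH", "OT", "CN", "HP", "RN"]
OUTCOME_RATES = {"HO": 0.15, "LT": 0.05, "DE": 0.04, "DS": 0.01, "OT": 0.10}


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


def zipf_vocabulary(prefix: str, n: int) -> Dict[str, float]:
    """Zipf-like marginal probabilities p_i proportional to 1/i."""
    raw = np.array([1.0 / (i + 1) for i in range(n)])
    p = raw / raw.sum()
    return {f"{prefix}_{i + 1:03d}": float(p[i]) for i in range(n)}


@dataclass(frozen=True)
class PlantedSignal:
    """A (drug, PT) pair reported at ``rr`` times its background rate.

    Optional demographic conditions restrict the excess risk to a subgroup
    (used to validate stratified analyses).
    """

    drug: str
    pt: str
    rr: float
    age_min: Optional[float] = None
    age_max: Optional[float] = None
    sex: Optional[str] = None


@dataclass
class SyntheticConfig:
    """Full generative specification for one synthetic bundle."""

    n_cases: int = 1000
    n_quarters: int = 4
    start_quarter: str = "2020Q1"
    drug_vocabulary: Dict[str, float] = field(
        default_factory=lambda: _default_drugs()
    )
    event_vocabulary: Dict[str, float] = field(
        default_factory=lambda: zipf_vocabulary("PT", 50)
    )
    planted_signals: List[PlantedSignal] = field(default_factory=list)
    duplicate_rate: float = 0.0
    missingness: Dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.30, "sex": 0.20, "weight": 0.50,
            "event_dt": 0.50, "ther_start_dt": 0.60,
        }
    )
    pts_per_report: Dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    extra_drugs_mean: float = 1.0
    n_soc: int = 5
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ConfigurationError("n_cases must be a positive integer")
        if self.n_quarters <= 0:
            raise ConfigurationError("n_quarters must be a positive integer")
        for name, vocab in (
            ("drug_vocabulary", self.drug_vocabulary),
            ("event_vocabulary", self.event_vocabulary),
        ):
            probs = np.array(list(vocab.values()), dtype=float)
            if len(probs) == 0 or np.any(probs < 0) or np.any(probs > 1):
                raise ConfigurationError(f"{name}: probabilities must lie in [0,1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"{name}: marginal probabilities sum to {probs.sum()!r}, not 1"
                )
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ConfigurationError("duplicate_rate must lie in [0,1)")
        for key, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"missingness[{key!r}] must lie in [0,1]")
        kprobs = np.array(list(self.pts_per_report.values()), dtype=float)
        if abs(kprobs.sum() - 1.0) > 1e-9 or np.any(kprobs < 0):
            raise ConfigurationError("pts_per_report: probabilities must sum to 1")
        if any(int(k) != k or k < 1 for k in self.pts_per_report):
            raise ConfigurationError("pts_per_report: counts must be positive integers")
        if max(self.pts_per_report) > len(self.event_vocabulary):
            raise ConfigurationError(
                "pts_per_report: max count exceeds event vocabulary size"
            )
        for sig in self.planted_signals:
            if sig.drug not in self.drug_vocabulary:
                raise ConfigurationError(
                    f"planted_signals: drug {sig.drug!r} not in drug_vocabulary"
                )
            if sig.pt not in self.event_vocabulary:
                raise ConfigurationError(
                    f"planted_signals: PT {sig.pt!r} not in event_vocabulary"
                )
            if sig.rr < 0:
                raise ConfigurationError("planted_signals: relative risk must be >= 0")

    def quarters(self) -> List[str]:
        year = int(self.start_quarter[:4])
        q = int(self.start_quarter[-1])
        labels = []
        for _ in range(self.n_quarters):
            labels.append(f"{year}Q{q}")
            q += 1
            if q == 5:
                year, q = year + 1, 1
        return labels

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_signals"] = [asdict(s) for s in self.planted_signals]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["planted_signals"] = [
            PlantedSignal(**s) for s in payload.get("planted_signals", [])
        ]
        payload["pts_per_report"] = {
            int(k): v for k, v in payload.get("pts_per_report", {}).items()
        }
        return cls(**payload)


def _default_drugs() -> Dict[str, float]:
    # one moderately common target drug plus nine background drugs
    names = ["TARGETDRUG"] + [f"DRUG_{c}" for c in "ABCDEFGHI"]
    probs = [0.10] + [0.10] * 9
    return dict(zip(names, probs))


@dataclass
class GroundTruth:
    """Per planted pair: baseline expectation, planted RR, realized count."""

    table: pd.DataFrame  # columns: drug, pt, rr, expected, realized

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _quarter_start(label: str) -> datetime.date:
    year, q = int(label[:4]), int(label[-1])
    return datetime.date(year, 3 * (q - 1) + 1, 1)


def _date_int(d: datetime.date) -> int:
    return d.year * 10000 + d.month * 100 + d.day


def _quarter_of(date_int: int, labels: Sequence[str]) -> str:
    year, month = date_int // 10000, (date_int // 100) % 100
    label = f"{year}Q{(month - 1) // 3 + 1}"
    return label if label in labels else labels[-1]


def generate_bundle(
    config: SyntheticConfig,
) -> Tuple[List[RawTables], GroundTruth]:
    """Generate quarterly :class:`RawTables` plus the planted-signal ground
    truth.  Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    labels = config.quarters()
    drugs = list(config.drug_vocabulary)
    drug_p = np.array([config.drug_vocabulary[d] for d in drugs])
    events = list(config.event_vocabulary)
    event_p = np.array([config.event_vocabulary[e] for e in events])
    miss = config.missingness

    caseids = np.array([str(10_000_000 + i) for i in range(n)])
    primaryids = np.char.add(caseids, "1")

    # report dates: uniform quarter, uniform day within quarter
    q_idx = rng.integers(0, len(labels), size=n)
    day_off = rng.integers(0, 89, size=n)
    fda_dt = np.array(
        [
            _date_int(_quarter_start(labels[q]) + datetime.timedelta(days=int(o)))
            for q, o in zip(q_idx, day_off)
        ]
    )

    # demographics (true values; units and missingness applied at encoding)
    age_true = rng.uniform(0.0, 90.0, size=n)
    sex_true = rng.choice(["F", "M"], size=n)
    weight_true = np.clip(rng.normal(70.0, 15.0, size=n), 3.0, 160.0)
    country = rng.choice(COUNTRIES, size=n)
    occp = rng.choice(OCCUPATIONS, size=n)

    age_unit = rng.choice(["YR", "MON", "DEC"], size=n, p=[0.7, 0.15, 0.15])
    wt_unit = rng.choice(["KG", "LBS"], size=n, p=[0.8, 0.2])
    age_missing = rng.random(n) < miss.get("age", 0.0)
    sex_missing = rng.random(n) < miss.get("sex", 0.0)
    wt_missing = rng.random(n) < miss.get("weight", 0.0)
    ev_missing = rng.random(n) < miss.get("event_dt", 0.0)
    ther_missing = rng.random(n) < miss.get("ther_start_dt", 0.0)

    # event and therapy dates: therapy starts `onset` days before the event,
    # the event precedes the report by up to 30 days
    ev_lag = rng.integers(0, 30, size=n)
    onset = rng.geometric(0.25, size=n) - 1  # mostly within the first week
    event_dt = np.empty(n, dtype=object)
    ther_dt = np.empty(n, dtype=object)
    for i in range(n):
        fdate = datetime.date(fda_dt[i] // 10000, (fda_dt[i] // 100) % 100, fda_dt[i] % 100)
        ed = fdate - datetime.timedelta(days=int(ev_lag[i]))
        event_dt[i] = "" if ev_missing[i] else str(_date_int(ed))
        td = ed - datetime.timedelta(days=int(onset[i]))
        ther_dt[i] = "" if ther_missing[i] else str(_date_int(td))

    # drugs: one primary suspect + Poisson extras with other roles
    ps_idx = rng.choice(len(drugs), size=n, p=drug_p)
    n_extra = rng.poisson(config.extra_drugs_mean, size=n)
    extra_idx = [rng.choice(len(drugs), size=k, p=drug_p) for k in n_extra]
    extra_roles = [rng.choice(["SS", "C", "I"], size=k) for k in n_extra]

    # PTs: weighted Gumbel top-k sampling without replacement per report
    k_vals = np.array(sorted(config.pts_per_report), dtype=int)
    k_p = np.array([config.pts_per_report[int(k)] for k in k_vals])
    k_per = rng.choice(k_vals, size=n, p=k_p)
    with np.errstate(divide="ignore"):
        logw = np.tile(np.log(event_p), (n, 1))
    event_index = {e: j for j, e in enumerate(events)}
    for sig in config.planted_signals:
        rows = ps_idx == drugs.index(sig.drug)
        if sig.age_min is not None:
            rows &= age_true >= sig.age_min
        if sig.age_max is not None:
            rows &= age_true < sig.age_max
        if sig.sex is not None:
            rows &= sex_true == sig.sex
        with np.errstate(divide="ignore"):
            logw[rows, event_index[sig.pt]] += math.log(sig.rr) if sig.rr > 0 else -np.inf
    gumbel = rng.gumbel(size=logw.shape)
    order = np.argsort(-(logw + gumbel), axis=1, kind="stable")
    pt_sets = [order[i, : k_per[i]] for i in range(n)]

    # outcomes: independent small-probability serious-outcome codes
    outc_rows: List[Tuple[str, str]] = []
    for code, rate in OUTCOME_RATES.items():
        hit = rng.random(n) < rate
        outc_rows.extend((primaryids[i], code) for i in np.nonzero(hit)[0])
    outc_rows.sort()

    # assemble canonical frames
    demo = pd.DataFrame(
        {
            "primaryid": primaryids,
            "caseid": caseids,
            "fda_dt": fda_dt,
            "event_dt": event_dt.astype(str),
            "sex": np.where(sex_missing, "", sex_true),
            "age": [
                "" if age_missing[i] else _encode_age(age_true[i], age_unit[i])
                for i in range(n)
            ],
            "age_cod": np.where(age_missing, "", age_unit),
            "wt": [
                "" if wt_missing[i] else _encode_weight(weight_true[i], wt_unit[i])
                for i in range(n)
            ],
            "wt_cod": np.where(wt_missing, "", wt_unit),
            "reporter_country": country,
            "occp_cod": occp,
        }
    )
    drug_rows = []
    ther_rows = []
    for i in range(n):
        pid = primaryids[i]
        drug_rows.append((pid, "1", drugs[ps_idx[i]], drugs[ps_idx[i]], "PS"))
        ther_rows.append((pid, "1", ther_dt[i]))
        for j, (di, role) in enumerate(zip(extra_idx[i], extra_roles[i]), start=2):
            drug_rows.append((pid, str(j), drugs[di], drugs[di], role))
            ther_rows.append((pid, str(j), ther_dt[i]))
    drug = pd.DataFrame(drug_rows, columns=list(CANONICAL_COLUMNS["drug"]))
    ther = pd.DataFrame(ther_rows, columns=list(CANONICAL_COLUMNS["ther"]))
    reac = pd.DataFrame(
        [
            (primaryids[i], events[j])
            for i in range(n)
            for j in sorted(pt_sets[i])
        ],
        columns=["primaryid", "pt"],
    )
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"])

    tables = _split_quarters(demo, drug, reac, outc, ther, labels)
    if config.duplicate_rate > 0:
        dup_seed = int(rng.integers(0, 2**31 - 1))
        tables = inject_duplicates(tables, config.duplicate_rate, dup_seed)

    truth = _ground_truth(config, drugs, ps_idx, pt_sets, event_index, event_p)
    return tables, truth


def _encode_age(years: float, unit: str) -> str:
    if unit == "YR":
        return str(int(round(years)))
    if unit == "MON":
        return str(int(round(years * 12)))
    return f"{years / 10.0:.2f}"  # DEC


def _encode_weight(kg: float, unit: str) -> str:
    if unit == "KG":
        return f"{kg:.1f}"
    return f"{kg / 0.45359237:.1f}"  # LBS


def _split_quarters(demo, drug, reac, outc, ther, labels) -> List[RawTables]:
    qmap = {
        pid: _quarter_of(int(dt), labels)
        for pid, dt in zip(demo["primaryid"], demo["fda_dt"])
    }
    out = []
    for label in labels:
        pids = {p for p, q in qmap.items() if q == label}
        out.append(
            RawTables(
                quarter=label,
                demo=demo[demo["primaryid"].isin(pids)].reset_index(drop=True),
                drug=drug[drug["primaryid"].isin(pids)].reset_index(drop=True),
                reac=reac[reac["primaryid"].isin(pids)].reset_index(drop=True),
                outc=outc[outc["primaryid"].isin(pids)].reset_index(drop=True),
                ther=ther[ther["primaryid"].isin(pids)].reset_index(drop=True),
            )
        )
    return out


def _ground_truth(config, drugs, ps_idx, pt_sets, event_index, event_p) -> GroundTruth:
    rows = []
    for sig in config.planted_signals:
        di = drugs.index(sig.drug)
        drug_reports = np.nonzero(ps_idx == di)[0]
        expected = len(drug_reports) * event_p[event_index[sig.pt]]
        realized = sum(
            1 for i in drug_reports if event_index[sig.pt] in pt_sets[i]
        )
        rows.append((sig.drug, sig.pt, sig.rr, float(expected), int(realized)))
    return GroundTruth(
        pd.DataFrame(rows, columns=["drug", "pt", "rr", "expected", "realized"])
    )


def inject_duplicates(
    tables: List[RawTables], rate: float, seed: int
) -> List[RawTables]:
    """Re-report ``floor(rate * n_cases)`` cases in a later quarter.

    Each chosen case gains one extra record with a strictly later FDA_DT and
    a larger PRIMARYID; all other fields (and all DRUG/REAC/OUTC/THER rows)
    are copied verbatim.  ``rate == 0`` returns the input unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("duplicate rate must lie in [0,1)")
    if rate == 0.0:
        return tables
    rng = np.random.default_rng(seed)
    labels = [t.quarter for t in tables]
    demo_all = pd.concat([t.demo for t in tables], ignore_index=True)
    n_cases = demo_all["caseid"].nunique()
    n_dup = int(math.floor(rate * n_cases))
    chosen = rng.choice(np.sort(demo_all["caseid"].unique()), size=n_dup, replace=False)
    by_quarter = {t.quarter: t for t in tables}
    originals = demo_all.set_index("caseid")
    new_rows: Dict[str, Dict[str, list]] = {
        q: {k: [] for k in ("demo", "drug", "reac", "outc", "ther")} for q in labels
    }
    for caseid in chosen:
        orig = originals.loc[caseid]
        old_pid = orig["primaryid"]
        new_pid = caseid + "2"
        old_dt = int(orig["fda_dt"])
        d = datetime.date(old_dt // 10000, (old_dt // 100) % 100, old_dt % 100)
        new_dt = _date_int(d + datetime.timedelta(days=int(rng.integers(30, 120))))
        dest = _quarter_of(new_dt, labels)
        row = orig.copy()
        row["primaryid"] = new_pid
        row["fda_dt"] = new_dt
        new_rows[dest]["demo"].append(
            {"caseid": caseid, **{k: row[k] for k in row.index}}
        )
        src_q = _quarter_of(old_dt, labels)
        src = by_quarter[src_q]
        for kind in ("drug", "reac", "outc", "ther"):
            frame = getattr(src, kind)
            for _, r in frame[frame["primaryid"] == old_pid].iterrows():
                rec = dict(r)
                rec["primaryid"] = new_pid
                new_rows[dest][kind].append(rec)
    out = []
    for t in tables:
        extra = new_rows[t.quarter]
        frames = {}
        for kind in ("demo", "drug", "reac", "outc", "ther"):
            base = getattr(t, kind)
            if extra[kind]:
                add = pd.DataFrame(extra[kind])[list(base.columns)]
                frames[kind] = pd.concat([base, add], ignore_index=True)
            else:
                frames[kind] = base
        out.append(RawTables(quarter=t.quarter, skipped=dict(t.skipped), **frames))
    return out


def write_bundle(tables: List[RawTables], outdir: str | Path) -> List[Path]:
    """Write quarterly "$"-delimited files in the FAERS ASCII dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in tables:
        year, q = t.quarter.split("Q")
        stem = f"{year[2:]}Q{q}"
        for kind in ("demo", "drug", "reac", "outc", "ther"):
            path = outdir / f"{kind.upper()}{stem}.txt"
            frame = getattr(t, kind)
            lines = ["$".join(_SOURCE_HEADERS[kind])]
            cols = list(CANONICAL_COLUMNS[kind])
            for row in frame.itertuples(index=False):
                lines.append("$".join(str(getattr(row, c)) for c in cols))
            path.write_text("\n".join(lines) + "\n", encoding="utf-8")
            written.append(path)
    return written


def synthetic_meddra_map(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic PT->HLT->HLGT->SOC table for the event vocabulary.

    PTs are assigned round-robin to ``config.n_soc`` synthetic organ classes.
    """
    rows = []
    for j, pt in enumerate(config.event_vocabulary):
        soc_i = j % config.n_soc + 1
        rows.append((pt, f"HLT_{j + 1:03d}", f"HLGT_{soc_i:02d}", f"SOC_{soc_i:02d}"))
    return pd.DataFrame(rows, columns=["PT", "HLT", "HLGT", "SOC"])
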