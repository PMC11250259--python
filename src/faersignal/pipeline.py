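"""Orchestration: cohort preparation, descriptive summaries, signal runs.

A :class:`Dataset` bundles everything the analyses need after ingestion:
the deduplicated per-report table with derived demographics, the distinct
(report, PT) pairs, the primary-suspect cohort id set and the MedDRA
hierarchy.  On top of it sit

* :func:`descriptive_summary` — counts/percentages by sex, age bin,
  reporter occupation, country, year, serious outcome and onset bin,
* :func:`run_analysis` — 2x2 tables, all four estimators, the joint screen
  and EBGM-descending ranking at PT or SOC level,
* :func:`stratified_runs` — the same analysis within age/sex/weight strata,
  with both cohort and background restricted to the stratum (a config
  switch keeps the global background instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .cases import (
    AGE_DESCRIPTIVE_BINS,
    AGE_STRATA_BINS,
    ONSET_BINS,
    WEIGHT_STRATA_BINS,
    assign_bin,
    build_case_table,
    deduplicate,
    select_target_reports,
)
from .hierarchy import MedDRAHierarchy
from .io import OUTCOME_LABELS, RawTables
from .mgps import GammaPoissonShrinker
from .stats import build_tables, compute_signals


@dataclass
class Dataset:
    """Deduplicated, cohort-annotated analysis inputs."""

    cases: pd.DataFrame          # all kept reports with derived fields
    pairs: pd.DataFrame          # distinct (primaryid, pt) pairs, kept reports
    outc: pd.DataFrame           # outcome codes of kept reports
    cohort_ids: Set[str]
    meddra: Optional[MedDRAHierarchy] = None
    counts: Dict[str, int] = field(default_factory=dict)
    keywords: tuple = ()

    @property
    def cohort_cases(self) -> pd.DataFrame:
        return self.cases[self.cases["primaryid"].isin(self.cohort_ids)]


def prepare_dataset(
    tables: Sequence[RawTables],
    keywords: Sequence[str],
    role: str = "PS",
    meddra: Optional[MedDRAHierarchy] = None,
) -> Dataset:
    """Concatenate quarters, deduplicate, select the cohort, derive fields.

    The audit trail in ``Dataset.counts`` records every filtering step:
    reports in -> after dedup -> cohort size -> distinct pairs.
    """
    demo = pd.concat([t.demo for t in tables], ignore_index=True)
    drug = pd.concat([t.drug for t in tables], ignore_index=True)
    reac = pd.concat([t.reac for t in tables], ignore_index=True)
    outc = pd.concat([t.outc for t in tables], ignore_index=True)
    ther = pd.concat([t.ther for t in tables], ignore_index=True)

    kept = deduplicate(demo)
    target = select_target_reports(drug, keywords, role) & kept
    cases = build_case_table(
        demo, kept, drug=drug, ther=ther, target_ids=target,
        keywords=keywords, role=role,
    )
    pairs = (
        reac[reac["primaryid"].isin(kept)][["primaryid", "pt"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    outc_kept = outc[outc["primaryid"].isin(kept)].reset_index(drop=True)
    return Dataset(
        cases=cases,
        pairs=pairs,
        outc=outc_kept,
        cohort_ids=target,
        meddra=meddra,
        keywords=tuple(keywords),
        counts={
            "reports_in": int(len(demo)),
            "deduplicated": int(len(kept)),
            "cohort": int(len(target)),
            "pairs": int(len(pairs)),
        },
    )


# --------------------------------------------------------------- descriptives

DEFAULT_PRECISION = {
    "sex": 1, "age": 1, "reporter": 1, "country": 2,
    "year": 2, "onset": 2, "outcomes": 1,
}

SEX_LABELS = {"F": "Female", "M": "Male", "UNK": "Unknown"}


def percentage_table(
    counts: Mapping[str, int], denominator: float, decimals: int
) -> pd.DataFrame:
    """Counts plus percentages of ``denominator`` rounded to ``decimals``."""
    cats = list(counts)
    vals = [int(counts[c]) for c in cats]
    pct = [
        round(100.0 * v / denominator, decimals) if denominator else np.nan
        for v in vals
    ]
    return pd.DataFrame({"category": cats, "count": vals, "percent": pct})


def descriptive_summary(
    cohort: pd.DataFrame,
    outc: Optional[pd.DataFrame] = None,
    precision: Optional[Mapping[str, int]] = None,
    outcome_denominator: str = "codes",
) -> Dict[str, pd.DataFrame]:
    """Tabulate the cohort's clinical characteristics.

    Percentages use the total deduplicated cohort size as denominator, except
    serious outcomes where one report may carry several outcome codes: there
    the denominator is the total number of outcome codes
    (``outcome_denominator="codes"``) or the report count (``"reports"``).
    Missing values get explicit Missing/Unknown rows.
    """
    prec = dict(DEFAULT_PRECISION)
    if precision:
        prec.update(precision)
    total = len(cohort)
    out: Dict[str, pd.DataFrame] = {}
    if total == 0:
        return out

    sex_counts = cohort["sex"].map(lambda s: SEX_LABELS.get(s, "Unknown")).value_counts()
    out["sex"] = percentage_table(
        {k: sex_counts.get(k, 0) for k in ("Female", "Male", "Unknown")},
        total, prec["sex"],
    )

    age_bins = cohort["age_years"].map(
        lambda v: assign_bin(v, AGE_DESCRIPTIVE_BINS) or "Missing"
    ).value_counts()
    labels = [b[2] for b in AGE_DESCRIPTIVE_BINS] + ["Missing"]
    out["age"] = percentage_table(
        {k: age_bins.get(k, 0) for k in labels}, total, prec["age"]
    )

    occ = cohort["occupation"].value_counts()
    out["reporter"] = percentage_table(dict(occ), total, prec["reporter"])

    country = cohort["country"].replace("", "Missing").value_counts()
    out["country"] = percentage_table(dict(country), total, prec["country"])

    years = cohort["year"].value_counts().sort_index()
    out["year"] = percentage_table(
        {str(y): n for y, n in years.items()}, total, prec["year"]
    )

    onset_bins = cohort["onset_days"].map(
        lambda v: assign_bin(v, ONSET_BINS) or "Unknown"
    ).value_counts()
    labels = [b[2] for b in ONSET_BINS] + ["Unknown"]
    out["onset"] = percentage_table(
        {k: onset_bins.get(k, 0) for k in labels}, total, prec["onset"]
    )

    if outc is not None:
        codes = outc[outc["primaryid"].isin(set(cohort["primaryid"]))]["outc_cod"]
        counts = codes.value_counts()
        denom = int(counts.sum()) if outcome_denominator == "codes" else total
        out["outcomes"] = percentage_table(
            {OUTCOME_LABELS.get(c, c): n for c, n in counts.items()},
            denom, prec["outcomes"],
        )
    return out


# ------------------------------------------------------------- signal running


@dataclass
class AnalysisConfig:
    """Knobs of one signal run; every choice is recorded in run metadata."""

    min_count: int = 3
    top_k: Optional[int] = None
    ic_variant: str = "plain"
    ic025_variant: str = "noren"
    yates: bool = True
    full_mgps: bool = False
    restrict_background: bool = True  # stratified runs only

    def metadata(self) -> Dict[str, object]:
        return {
            "min_count": self.min_count,
            "top_k": self.top_k,
            "ic_variant": self.ic_variant,
            "ic025_variant": self.ic025_variant,
            "yates_correction": self.yates,
            "full_mgps": self.full_mgps,
            "stratum_restricted_background": self.restrict_background,
        }


@dataclass
class RankedSignalTable:
    """Full per-term results plus the screened-positive subset, EBGM-ranked."""

    full: pd.DataFrame
    positives: pd.DataFrame
    level: str
    metadata: Dict[str, object] = field(default_factory=dict)


def _rank(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.sort_values(
        ["ebgm", "a", "term"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)


def run_analysis(
    dataset: Dataset,
    level: str = "PT",
    config: Optional[AnalysisConfig] = None,
) -> RankedSignalTable:
    """Build tables, compute every estimator, screen and rank by EBGM."""
    config = config or AnalysisConfig()
    if not dataset.cohort_ids:
        raise ValueError(
            "cohort is empty: no reports matched the drug keywords "
            f"{list(dataset.keywords) or '<unspecified>'}"
        )
    tables = build_tables(
        dataset.cohort_ids, dataset.pairs, level=level,
        meddra=dataset.meddra, min_count=config.min_count,
    )
    shrinker = None
    if config.full_mgps and len(tables) >= 2:
        a = tables["a"].to_numpy(dtype=float)
        n = (tables["a"] + tables["b"] + tables["c"] + tables["d"]).to_numpy(dtype=float)
        e = (tables["a"] + tables["b"]).to_numpy(float) * (
            tables["a"] + tables["c"]
        ).to_numpy(float) / n
        shrinker = GammaPoissonShrinker().fit(a, e)
    results = compute_signals(
        tables,
        ic_variant=config.ic_variant,
        ic025_variant=config.ic025_variant,
        yates=config.yates,
        min_count=config.min_count,
        shrinker=shrinker,
    )
    full = _rank(results)
    positives = _rank(results[results["signal"] & ~results["low_count"]])
    if config.top_k is not None:
        positives = positives.head(config.top_k).reset_index(drop=True)
    meta = config.metadata()
    meta["level"] = level
    return RankedSignalTable(full=full, positives=positives, level=level, metadata=meta)


# --------------------------------------------------------------- stratification


@dataclass(frozen=True)
class StratumSpec:
    """One stratum: a half-open numeric bin (age/weight) or a sex value."""

    dimension: str               # "age" | "weight" | "sex"
    label: str
    lower: Optional[float] = None
    upper: Optional[float] = None
    value: Optional[str] = None  # sex strata

    def mask(self, cases: pd.DataFrame) -> pd.Series:
        if self.dimension == "sex":
            return cases["sex"] == self.value
        col = {"age": "age_years", "weight": "weight_kg"}[self.dimension]
        v = cases[col]
        m = v.notna()
        if self.lower is not None:
            m &= v >= self.lower
        if self.upper is not None:
            m &= v < self.upper
        return m


def default_strata() -> List[StratumSpec]:
    """Age, sex and weight strata of the standard sensitivity analysis."""
    strata = [
        StratumSpec("age", label, lower=lo, upper=hi)
        for lo, hi, label in AGE_STRATA_BINS
    ]
    strata += [
        StratumSpec("sex", "male", value="M"),
        StratumSpec("sex", "female", value="F"),
    ]
    strata += [
        StratumSpec("weight", label, lower=lo, upper=hi)
        for lo, hi, label in WEIGHT_STRATA_BINS
    ]
    return strata


def _check_disjoint(strata: Sequence[StratumSpec]) -> None:
    by_dim: Dict[str, List[StratumSpec]] = {}
    for s in strata:
        by_dim.setdefault(s.dimension, []).append(s)
    for dim, specs in by_dim.items():
        if dim == "sex":
            values = [s.value for s in specs]
            if len(values) != len(set(values)):
                raise ValueError(f"overlapping sex strata: {values}")
            continue
        spans = sorted(
            ((s.lower if s.lower is not None else -np.inf,
              s.upper if s.upper is not None else np.inf, s.label) for s in specs)
        )
        for (lo1, hi1, l1), (lo2, hi2, l2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError(
                    f"overlapping {dim} strata: {l1!r} and {l2!r}"
                )


def stratified_runs(
    dataset: Dataset,
    strata: Optional[Sequence[StratumSpec]] = None,
    level: str = "PT",
    config: Optional[AnalysisConfig] = None,
) -> Dict[str, RankedSignalTable]:
    """Run the analysis per stratum.

    Both cohort and background are restricted to the stratum before table
    construction (``config.restrict_background=False`` keeps the global
    background).  Strata with no cohort reports yield empty tables rather
    than errors.
    """
    config = config or AnalysisConfig()
    strata = list(strata) if strata is not None else default_strata()
    _check_disjoint(strata)
    out: Dict[str, RankedSignalTable] = {}
    for spec in strata:
        key = f"{spec.dimension}:{spec.label}"
        in_stratum = set(dataset.cases.loc[spec.mask(dataset.cases), "primaryid"])
        cohort = dataset.cohort_ids & in_stratum
        if config.restrict_background:
            pairs = dataset.pairs[dataset.pairs["primaryid"].isin(in_stratum)]
        else:
            pairs = dataset.pairs[
                dataset.pairs["primaryid"].isin(in_stratum)
                | ~dataset.pairs["primaryid"].isin(dataset.cohort_ids)
            ]
        if not cohort:
            empty = pd.DataFrame(
                columns=["term", "level", "a", "b", "c", "d", "low_count"]
            )
            out[key] = RankedSignalTable(
                full=empty, positives=empty, level=level,
                metadata={**config.metadata(), "level": level, "stratum": key,
                          "empty": True},
            )
            continue
        sub = Dataset(
            cases=dataset.cases[dataset.cases["primaryid"].isin(in_stratum)],
            pairs=pairs.reset_index(drop=True),
            outc=dataset.outc,
            cohort_ids=cohort,
            meddra=dataset.meddra,
            keywords=dataset.keywords,
        )
        result = run_analysis(sub, level=level, config=config)
        result.metadata["stratum"] = key
        out[key] = result
    return out
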