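"""Disproportionality statistics on 2x2 drug-event contingency tables.

For one drug-term pair the table cells are

    a = reports with the target drug AND the term
    b = target-drug reports without the term
    c = other-drug reports with the term
    d = other-drug reports without the term

with N = a+b+c+d and independence expectation E = (a+b)(a+c)/N.  Four
estimators are computed:

* ROR = ad/bc with a log-normal Wald 95% CI,
* PRR = [a/(a+b)] / [c/(c+d)] with its log-normal CI and a Pearson
  chi-square (Yates-corrected by default),
* BCPNN information component IC; the "plain" variant is
  log2(a/E) (the maximum-likelihood IC, which satisfies IC = log2(EBGM)
  for the simplified shrinker), the "noren" variant applies +0.5 shrinkage
  to both numerator and expectation,
* EBGM; in simplified form the observed/expected ratio a/E, in full
  empirical-Bayes form the posterior geometric mean under the fitted
  gamma-mixture prior (see :mod:`faersignal.mgps`).

A pair is flagged as a joint signal when all of: a >= 3, ROR and PRR lower
95% bounds > 1, chi-square >= 4, IC025 > 0, and EBGM > 2.

All estimator functions are vectorized over numpy arrays of cell counts;
scalar inputs return scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hierarchy import MedDRAHierarchy, UNMAPPED

Z95 = 1.959963984540054  # two-sided 95% normal quantile
Z90 = 1.6448536269514722  # one-sided 5% normal quantile

SIGNAL_CRITERIA = ("n>=3", "ror_low>1", "prr_low>1", "chi2>=4", "ic025>0", "ebgm>2")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-term pair at one MedDRA level."""

    a: int
    b: int
    c: int
    d: int
    term: str = ""
    level: str = "PT"

    def __post_init__(self):
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {cell} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty table (N=0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        return (self.a + self.b) * (self.a + self.c) / self.n

    def cells(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class DisproResult:
    """All four estimators plus the joint screen for one term."""

    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    expected: float
    corrected: bool = False
    flags: Dict[str, bool] = field(default_factory=dict)
    signal: bool = False


def _as_arrays(a, b, c, d):
    arrs = [np.asarray(x, dtype=float) for x in (a, b, c, d)]
    scalar = all(x.ndim == 0 for x in arrs)
    return [np.atleast_1d(x) for x in arrs], scalar


def _maybe_scalar(scalar, *values):
    if scalar:
        out = tuple(np.asarray(v).reshape(-1)[0] for v in values)
    else:
        out = values
    return out if len(out) > 1 else out[0]


def ror(a, b, c, d, z: float = Z95):
    """Reporting odds ratio with log-normal CI.

    Zero cells get the Haldane 0.5 continuity correction applied to all four
    cells; the returned ``corrected`` mask marks affected tables.
    """
    (a_, b_, c_, d_), scalar = _as_arrays(a, b, c, d)
    corrected = (a_ == 0) | (b_ == 0) | (c_ == 0) | (d_ == 0)
    h = np.where(corrected, 0.5, 0.0)
    aa, bb, cc, dd = a_ + h, b_ + h, c_ + h, d_ + h
    est = (aa * dd) / (bb * cc)
    se = np.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    low = est * np.exp(-z * se)
    high = est * np.exp(z * se)
    return _maybe_scalar(scalar, est, low, high, corrected)


def prr(a, b, c, d, z: float = Z95):
    """Proportional reporting ratio with log-normal CI (Haldane on zeros)."""
    (a_, b_, c_, d_), scalar = _as_arrays(a, b, c, d)
    corrected = (a_ == 0) | (c_ == 0)
    h = np.where(corrected, 0.5, 0.0)
    aa, bb, cc, dd = a_ + h, b_ + h, c_ + h, d_ + h
    est = (aa / (aa + bb)) / (cc / (cc + dd))
    se = np.sqrt(1.0 / aa - 1.0 / (aa + bb) + 1.0 / cc - 1.0 / (cc + dd))
    low = est * np.exp(-z * se)
    high = est * np.exp(z * se)
    return _maybe_scalar(scalar, est, low, high, corrected)


def chi_square(a, b, c, d, yates: bool = True):
    """Pearson chi-square over the four cells, optional Yates correction.

    Tables with a zero expected cell return NaN (undefined).
    """
    (a_, b_, c_, d_), scalar = _as_arrays(a, b, c, d)
    n = a_ + b_ + c_ + d_
    obs = np.stack([a_, b_, c_, d_])
    exp = np.stack(
        [
            (a_ + b_) * (a_ + c_),
            (a_ + b_) * (b_ + d_),
            (c_ + d_) * (a_ + c_),
            (c_ + d_) * (b_ + d_),
        ]
    ) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(obs - exp)
        if yates:
            dev = np.maximum(dev - 0.5, 0.0)
        stat = np.sum(dev**2 / exp, axis=0)
    stat = np.where((exp <= 0).any(axis=0), np.nan, stat)
    return _maybe_scalar(scalar, stat)


def bcpnn_ic(a, b, c, d, variant: str = "plain", ic025_variant: str = "noren"):
    """BCPNN information component and its lower 95% credibility bound.

    ``variant``:
      * ``"plain"`` — IC = log2(aN/((a+b)(a+c))) = log2(a/E); a=0 gives -inf.
      * ``"noren"`` — IC = log2((a+0.5)/(E+0.5)) (shrinkage s=0.5).

    ``ic025_variant``:
      * ``"noren"`` — IC - 3.3(a+0.5)^(-1/2) - 2.0(a+0.5)^(-3/2).
      * ``"gamma"`` — log2 of the exact 2.5% quantile of the
        Gamma(a+0.5, E+0.5) posterior on the observed/expected ratio.
    """
    (a_, b_, c_, d_), scalar = _as_arrays(a, b, c, d)
    n = a_ + b_ + c_ + d_
    expected = (a_ + b_) * (a_ + c_) / n
    if variant == "plain":
        with np.errstate(divide="ignore"):
            ic = np.log2(np.where(a_ > 0, a_, np.nan) / expected)
        ic = np.where(a_ > 0, ic, -np.inf)
    elif variant == "noren":
        ic = np.log2((a_ + 0.5) / (expected + 0.5))
    else:
        raise ValueError(f"unknown IC variant {variant!r}")
    if ic025_variant == "noren":
        ic025 = ic - 3.3 * (a_ + 0.5) ** -0.5 - 2.0 * (a_ + 0.5) ** -1.5
    elif ic025_variant == "gamma":
        lam = sps.gamma.ppf(0.025, a_ + 0.5, scale=1.0 / (expected + 0.5))
        ic025 = np.log2(lam)
    else:
        raise ValueError(f"unknown IC025 variant {ic025_variant!r}")
    return _maybe_scalar(scalar, ic, ic025)


def ebgm_simplified(a, b, c, d, z: float = Z90):
    """Simplified (observed/expected) EBGM with a log-normal lower bound.

    EBGM = aN/((a+b)(a+c)) = a/E; a=0 gives 0 (flagged downstream).  EBGM05
    uses the same log standard error as the ROR, at the one-sided level ``z``.
    """
    (a_, b_, c_, d_), scalar = _as_arrays(a, b, c, d)
    n = a_ + b_ + c_ + d_
    expected = (a_ + b_) * (a_ + c_) / n
    ebgm = np.where(a_ > 0, a_ / expected, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_)
        low = np.where(a_ > 0, ebgm * np.exp(-z * se), 0.0)
    return _maybe_scalar(scalar, ebgm, low)


def screen_signal(
    a, ror_low, prr_low, chi2, ic025, ebgm, min_count: int = 3
) -> Tuple[bool, List[str]]:
    """Joint positivity screen; returns (flag, list of failed criteria)."""
    checks = {
        "n>=3": a >= min_count,
        "ror_low>1": ror_low > 1.0,
        "prr_low>1": prr_low > 1.0,
        "chi2>=4": bool(chi2 >= 4.0) if not np.isnan(chi2) else False,
        "ic025>0": ic025 > 0.0,
        "ebgm>2": ebgm > 2.0,
    }
    failed = [name for name, ok in checks.items() if not ok]
    return (not failed), failed


def build_tables(
    cohort_ids: Set[str],
    pairs: pd.DataFrame,
    level: str = "PT",
    meddra: Optional[MedDRAHierarchy] = None,
    min_count: int = 3,
) -> pd.DataFrame:
    """Build per-term 2x2 tables from (report, PT) pairs.

    The counting unit is the distinct (report, term) pair: duplicate terms
    within a report count once; at SOC level a report counts once per SOC
    even when several of its PTs map there.  Unmappable PTs at SOC level go
    to the "Unmapped" sentinel.  Returns a frame with columns term, a, b, c,
    d, low_count (a < min_count, excluded from screening but retained).
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be PT or SOC, got {level!r}")
    df = pairs[["primaryid", "pt"]].copy()
    if level == "SOC":
        if meddra is None:
            raise ValueError("SOC-level tables require a MedDRA hierarchy")
        df["term"] = df["pt"].map(meddra.soc)
    else:
        df["term"] = df["pt"]
    df = df[["primaryid", "term"]].drop_duplicates()
    in_cohort = df["primaryid"].isin(cohort_ids)
    total_cohort = int(in_cohort.sum())
    total_background = int(len(df) - total_cohort)
    a_counts = df.loc[in_cohort, "term"].value_counts()
    c_counts = df.loc[~in_cohort, "term"].value_counts()
    terms = sorted(set(a_counts.index))
    out = pd.DataFrame(
        {
            "term": terms,
            "a": [int(a_counts.get(t, 0)) for t in terms],
            "c": [int(c_counts.get(t, 0)) for t in terms],
        }
    )
    out["b"] = total_cohort - out["a"]
    out["d"] = total_background - out["c"]
    out["level"] = level
    out["low_count"] = out["a"] < min_count
    return out[["term", "level", "a", "b", "c", "d", "low_count"]]


def compute_signals(
    tables: pd.DataFrame,
    ic_variant: str = "plain",
    ic025_variant: str = "noren",
    yates: bool = True,
    min_count: int = 3,
    shrinker=None,
) -> pd.DataFrame:
    """Compute all estimators and the joint screen for a table frame.

    ``shrinker`` is an optional fitted :class:`~faersignal.mgps.
    GammaPoissonShrinker`; when given, full empirical-Bayes EBGM/EB05 replace
    the simplified observed/expected form.
    """
    a = tables["a"].to_numpy(dtype=float)
    b = tables["b"].to_numpy(dtype=float)
    c = tables["c"].to_numpy(dtype=float)
    d = tables["d"].to_numpy(dtype=float)
    n = a + b + c + d
    expected = (a + b) * (a + c) / n
    ror_est, ror_lo, ror_hi, corrected = ror(a, b, c, d)
    prr_est, prr_lo, prr_hi, _ = prr(a, b, c, d)
    chi2 = chi_square(a, b, c, d, yates=yates)
    ic, ic025 = bcpnn_ic(a, b, c, d, variant=ic_variant, ic025_variant=ic025_variant)
    if shrinker is not None:
        ebgm = shrinker.ebgm(a, expected)
        ebgm05 = shrinker.eb05(a, expected)
    else:
        ebgm, ebgm05 = ebgm_simplified(a, b, c, d)
    out = tables.copy()
    out["expected"] = expected
    out["ror"], out["ror_low"], out["ror_high"] = ror_est, ror_lo, ror_hi
    out["prr"], out["prr_low"], out["prr_high"] = prr_est, prr_lo, prr_hi
    out["chi2"] = chi2
    out["ic"], out["ic025"] = ic, ic025
    out["ebgm"], out["ebgm05"] = ebgm, ebgm05
    out["corrected"] = corrected
    flags = []
    reasons = []
    for i in range(len(out)):
        sig, failed = screen_signal(
            a[i], ror_lo[i], prr_lo[i], chi2[i], ic025[i], np.asarray(ebgm)[i],
            min_count=min_count,
        )
        flags.append(sig)
        reasons.append(";".join(failed))
    out["signal"] = flags
    out["failed_criteria"] = reasons
    return out


def dispro_result(table: ContingencyTable, **kwargs) -> DisproResult:
    """Convenience scalar wrapper returning a :class:`DisproResult`."""
    frame = pd.DataFrame(
        {"term": [table.term], "level": [table.level],
         "a": [table.a], "b": [table.b], "c": [table.c], "d": [table.d],
         "low_count": [False]}
    )
    row = compute_signals(frame, **kwargs).iloc[0]
    failed = row["failed_criteria"].split(";") if row["failed_criteria"] else []
    return DisproResult(
        table=table,
        ror=row["ror"], ror_low=row["ror_low"], ror_high=row["ror_high"],
        prr=row["prr"], prr_low=row["prr_low"], prr_high=row["prr_high"],
        chi2=row["chi2"], ic=row["ic"], ic025=row["ic025"],
        ebgm=row["ebgm"], ebgm05=row["ebgm05"], expected=row["expected"],
        corrected=bool(row["corrected"]),
        flags={name: name not in failed for name in SIGNAL_CRITERIA},
        signal=bool(row["signal"]),
    )
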