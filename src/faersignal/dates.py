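"""FAERS date handling.

FAERS encodes dates as integers in the YYYYMMDD dialect, but many fields are
only partially known and arrive as YYYY or YYYYMM.  Day-level arithmetic
(time-to-onset) must never fabricate a day, so parsed dates carry an explicit
precision flag and subtraction is only defined between two day-precise dates.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional

DAY = "day"
MONTH = "month"
YEAR = "year"


@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to day, month or year precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return DAY
        if self.month is not None:
            return MONTH
        return YEAR

    def as_date(self) -> datetime.date:
        if self.precision != DAY:
            raise ValueError(f"date {self} is not day-precise")
        return datetime.date(self.year, self.month, self.day)

    def as_int(self) -> int:
        if self.precision == DAY:
            return self.year * 10000 + self.month * 100 + self.day
        if self.precision == MONTH:
            return self.year * 100 + self.month
        return self.year


def parse_faers_date(raw) -> Optional[PartialDate]:
    """Parse a YYYYMMDD / YYYYMM / YYYY value; invalid or blank -> ``None``."""
    if raw is None:
        return None
    s = str(raw).strip()
    if s.endswith(".0"):  # float round-trip through pandas
        s = s[:-2]
    if not s or not s.isdigit():
        return None
    try:
        if len(s) == 8:
            d = PartialDate(int(s[:4]), int(s[4:6]), int(s[6:8]))
            d.as_date()  # calendar validation
            return d
        if len(s) == 6:
            y, m = int(s[:4]), int(s[4:6])
            if not 1 <= m <= 12:
                return None
            return PartialDate(y, m)
        if len(s) == 4:
            return PartialDate(int(s))
    except ValueError:
        return None
    return None


def days_between(later: Optional[PartialDate], earlier: Optional[PartialDate]) -> Optional[int]:
    """``later - earlier`` in days; ``None`` unless both are day-precise."""
    if later is None or earlier is None:
        return None
    if later.precision != DAY or earlier.precision != DAY:
        return None
    return (later.as_date() - earlier.as_date()).days
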