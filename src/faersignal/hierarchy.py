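"""MedDRA hierarchy lookup.

MedDRA is licensed, so the mapping table is user-supplied as a 4-column TSV
(PT, HLT, HLGT, SOC).  Lookup is case-insensitive on the preferred term;
terms absent from the map resolve to the :data:`UNMAPPED` sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import pandas as pd

UNMAPPED = "Unmapped"

REQUIRED_COLUMNS = ("PT", "HLT", "HLGT", "SOC")


def _norm(term: str) -> str:
    return " ".join(str(term).split()).upper()


@dataclass
class MedDRAHierarchy:
    """PT -> (HLT, HLGT, SOC) mapping with case-insensitive PT lookup."""

    _map: Dict[str, Tuple[str, str, str]] = field(default_factory=dict)

    def add(self, pt: str, hlt: str, hlgt: str, soc: str) -> None:
        key = _norm(pt)
        existing = self._map.get(key)
        if existing is not None and existing[2] != soc:
            raise ValueError(
                f"conflicting SOC mapping for PT {pt!r}: {existing[2]!r} vs {soc!r}"
            )
        self._map[key] = (hlt, hlgt, soc)

    def soc(self, pt: str) -> str:
        entry = self._map.get(_norm(pt))
        return entry[2] if entry is not None else UNMAPPED

    def hlt(self, pt: str) -> str:
        entry = self._map.get(_norm(pt))
        return entry[0] if entry is not None else UNMAPPED

    def hlgt(self, pt: str) -> str:
        entry = self._map.get(_norm(pt))
        return entry[1] if entry is not None else UNMAPPED

    def __contains__(self, pt: str) -> bool:
        return _norm(pt) in self._map

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MedDRAHierarchy":
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"MedDRA map missing columns: {missing}")
        # detect PTs mapped to >1 SOC before building, so the error lists them all
        norm_pt = frame["PT"].map(_norm)
        socs_per_pt = frame.groupby(norm_pt)["SOC"].nunique()
        conflicts = sorted(socs_per_pt.index[socs_per_pt > 1])
        if conflicts:
            raise ValueError(
                "PTs mapped to more than one SOC: " + ", ".join(conflicts)
            )
        hier = cls()
        for row in frame.itertuples(index=False):
            hier.add(row.PT, row.HLT, row.HLGT, row.SOC)
        return hier


def read_meddra_map(path: str | Path) -> MedDRAHierarchy:
    """Read a tab-separated PT/HLT/HLGT/SOC table into a hierarchy."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    frame.columns = [c.strip().upper() for c in frame.columns]
    return MedDRAHierarchy.from_frame(frame)
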