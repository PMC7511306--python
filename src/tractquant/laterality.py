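"""Hemispheric laterality index over paired left/right scalars.

LI = (L - R) / (L + R) for any non-negative left/right quantity (streamline
count or voxel volume).  LI ranges from -1 (completely right-lateralized)
to +1 (completely left-lateralized).  When L + R = 0 the index is
*undefined* and flagged as such -- never silently reported as 0, which
would fabricate symmetry from absent data.  The cohort summary is the
arithmetic mean of the defined per-subject LIs (not the LI of pooled
totals), matching the per-subject presentation conventional for tract
asymmetry studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "LateralityRecord",
    "CohortLaterality",
    "laterality_index",
    "cohort_laterality",
    "laterality_report",
]


def laterality_index(left_value: float, right_value: float) -> Optional[float]:
    """(L - R) / (L + R), or ``None`` when L + R = 0 (undefined).

    Raises ``ValueError`` for negative inputs.
    """
    if left_value < 0 or right_value < 0:
        raise ValueError("laterality inputs must be non-negative")
    total = left_value + right_value
    if total == 0:
        return None
    return (left_value - right_value) / total


@dataclass(frozen=True)
class LateralityRecord:
    """One subject's paired left/right measurement."""

    subject_id: str
    left_value: float
    right_value: float

    def __post_init__(self) -> None:
        if self.left_value < 0 or self.right_value < 0:
            raise ValueError("laterality inputs must be non-negative")

    @property
    def li(self) -> Optional[float]:
        return laterality_index(self.left_value, self.right_value)

    @property
    def defined(self) -> bool:
        return self.left_value + self.right_value > 0


@dataclass(frozen=True)
class CohortLaterality:
    """Per-subject LIs plus the cohort mean over defined records."""

    per_subject: Tuple[Tuple[str, Optional[float]], ...]
    mean_li: float
    n_defined: int
    n_undefined: int


def cohort_laterality(records: Sequence[LateralityRecord]) -> CohortLaterality:
    """Per-subject LI list and the arithmetic mean of the defined LIs.

    Undefined records (L + R = 0) are excluded from the mean and reported
    in ``n_undefined``.  Raises ``ValueError`` when no record is defined.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    per_subject: List[Tuple[str, Optional[float]]] = [
        (r.subject_id, r.li) for r in records
    ]
    defined = [li for _, li in per_subject if li is not None]
    if not defined:
        raise ValueError("laterality undefined for every record (all L+R = 0)")
    return CohortLaterality(
        per_subject=tuple(per_subject),
        mean_li=sum(defined) / len(defined),
        n_defined=len(defined),
        n_undefined=len(records) - len(defined),
    )


def laterality_report(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-subject ``li_count`` and ``li_volume`` columns.

    Expects columns ``subject_id, left_count, right_count, left_volume,
    right_volume``; undefined LIs appear as NA.  A trailing ``MEAN`` row
    carries the cohort means over the defined values.
    """
    required = ["subject_id", "left_count", "right_count",
                "left_volume", "right_volume"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"laterality table is missing columns {missing}")
    out = table[required].copy()
    for basis in ("count", "volume"):
        out[f"li_{basis}"] = [
            laterality_index(l, r)
            for l, r in zip(out[f"left_{basis}"], out[f"right_{basis}"])
        ]
    mean_row = {"subject_id": "MEAN"}
    for basis in ("count", "volume"):
        col = out[f"li_{basis}"].dropna()
        if col.empty:
            raise ValueError(f"laterality undefined for every subject ({basis})")
        mean_row[f"li_{basis}"] = col.mean()
    return pd.concat([out, pd.DataFrame([mean_row])], ignore_index=True)
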