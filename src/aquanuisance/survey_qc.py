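"""Survey quality control and derived respondent scores.

Implements the data-preparation rules of the nuisance-perception analysis:
records without a completed willingness-to-pay section are dropped, protest
allocations (more than 100 activity points) are dropped, fully blank records
are dropped; the lowest-level tick variant (used where the nuisance question
asked only for the lowest bothersome level) is expanded by a monotone fill;
the NEP score is the arithmetic mean of the answered 1-5 Likert items.

The analysis-ready shape is a long table with one row per respondent x
growth level (optionally x activity, carrying the activity-point weight).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .synthetic_survey import GROWTH_LEVELS, SurveyResponse

__all__ = [
    "QcReport",
    "CleanRecord",
    "filter_responses",
    "monotone_fill_lowest",
    "nep_score",
    "clean_records",
    "to_long_nuisance",
]

RULE_ORDER = ("wtp_incomplete", "protest", "blank")


@dataclass(frozen=True)
class QcReport:
    """Per-site accounting of the filtering rules."""

    site_label: str
    total: int
    retained: int
    removed: dict[str, int]

    @property
    def retention_pct(self) -> int:
        # round half up, matching how the retention percentages are printed
        return int(math.floor(100.0 * self.retained / self.total + 0.5))

    def to_json(self) -> str:
        return json.dumps({
            "site": self.site_label,
            "total": self.total,
            "retained": self.retained,
            "retention_pct": self.retention_pct,
            "removed": dict(self.removed),
        }, indent=2)


@dataclass(frozen=True)
class CleanRecord:
    """A retained respondent with derived scores attached."""

    response: SurveyResponse
    nep_score: Optional[float]

    @property
    def nuisance_observations(self) -> list[tuple[int, int]]:
        """(growth_level, nuisance 0/1) pairs; empty for don't-know."""
        if self.response.dont_know:
            return []
        return [(L, int(self.response.nuisance_ticks[L - 1])) for L in GROWTH_LEVELS]


def filter_responses(records: Sequence[SurveyResponse]) -> tuple[list[SurveyResponse], QcReport]:
    """Apply the three removal rules in order and account for each.

    Rules: (1) willingness-to-pay section not completed; (2) protest
    allocation, i.e. activity points summing above 100; (3) fully blank
    record.  Each removal is counted against the first rule it violates.
    """
    if not records:
        raise ValueError("filter_responses requires a non-empty record sequence")
    removed = {rule: 0 for rule in RULE_ORDER}
    retained: list[SurveyResponse] = []
    for r in records:
        if not r.wtp_complete:
            removed["wtp_incomplete"] += 1
        elif r.is_protest:
            removed["protest"] += 1
        elif r.is_blank:
            removed["blank"] += 1
        else:
            retained.append(r)
    report = QcReport(
        site_label=records[0].site_label,
        total=len(records),
        retained=len(retained),
        removed=removed,
    )
    return retained, report


def monotone_fill_lowest(ticks: Sequence[Optional[int]]) -> tuple[Optional[int], ...]:
    """Expand a lowest-level tick: every level at or above it becomes 1.

    Used for the site where the question asked only for the lowest growth
    level perceived as a nuisance, leaving higher levels unticked.  An
    all-unticked (or don't-know) input is returned unchanged; more than one
    tick is inconsistent with that question variant and raises.
    """
    ticks = tuple(ticks)
    if len(ticks) != len(GROWTH_LEVELS):
        raise ValueError("expected one tick state per growth level")
    if all(t is None for t in ticks):
        return ticks
    n_ticked = sum(1 for t in ticks if t == 1)
    if n_ticked > 1:
        raise ValueError("lowest-level question variant allows at most one tick")
    if n_ticked == 0:
        return ticks
    first = next(i for i, t in enumerate(ticks) if t == 1)
    return tuple(1 if i >= first else 0 for i in range(len(ticks)))


def nep_score(items: Sequence[Optional[int]]) -> Optional[float]:
    """Arithmetic mean of the answered NEP items on the 1-5 scale.

    Missing items are ignored; with no answered items the score is missing
    (the record is flagged, not dropped).
    """
    answered = [i for i in items if i is not None]
    if not answered:
        return None
    for v in answered:
        if not 1 <= v <= 5:
            raise ValueError(f"NEP item {v} outside the 1-5 scale")
    return sum(answered) / len(answered)


def clean_records(records: Sequence[SurveyResponse], monotone_fill: bool = False,
                  reverse_coded: Sequence[int] = ()) -> list[CleanRecord]:
    """Attach derived scores; optionally expand lowest-level ticks.

    ``reverse_coded`` lists 0-based NEP item indices to flip (6 - x) before
    scoring, for real data whose items are not pre-oriented.
    """
    out = []
    for r in records:
        if monotone_fill:
            r = replace(r, nuisance_ticks=monotone_fill_lowest(r.nuisance_ticks))
        items = list(r.nep_items)
        for idx in reverse_coded:
            if items[idx] is not None:
                items[idx] = 6 - items[idx]
        out.append(CleanRecord(response=r, nep_score=nep_score(items)))
    return out


def to_long_nuisance(records: Sequence[CleanRecord], weighted: bool = False) -> pd.DataFrame:
    """Long analysis table.

    Unweighted: one row per respondent x growth level.  Weighted: one row
    per respondent x growth level x activity with ``activity_weight`` =
    points/100; zero-weight rows are dropped.  Respondents who answered
    "I don't know" contribute no rows.
    """
    rows = []
    for rec in records:
        r = rec.response
        for L, nuis in rec.nuisance_observations:
            base = {
                "respondent_id": r.respondent_id,
                "site": r.site_label,
                "respondent_type": r.respondent_type,
                "nep_score": rec.nep_score,
                "growth_level": L,
                "nuisance": nuis,
            }
            if weighted:
                for a, pts in r.activity_points.items():
                    if pts > 0:
                        rows.append({**base, "activity": a, "activity_weight": pts / 100.0})
            else:
                rows.append(base)
    cols = ["respondent_id", "site", "respondent_type", "nep_score",
            "growth_level", "nuisance"] + (["activity", "activity_weight"] if weighted else [])
    return pd.DataFrame(rows, columns=cols)
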