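"""Time to onset: days from drug start to adverse-event onset.

Records without a drug start date or case event date, with an onset
before the start (aberrant), or with only partial-precision dates are
excluded, each with a counted reason.  Summaries report median and
quartiles (type-7 linear interpolation) and cumulative onset proportions
within 30 and 90 days.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional, Sequence, Union

import numpy as np

from .model import SafetyReport
from .signal_stats import EventPredicate


class ExclusionReason(str, enum.Enum):
    MISSING_START = "missing_start"
    MISSING_EVENT = "missing_event"
    NEGATIVE_INTERVAL = "negative_interval"
    PARTIAL_DATE = "partial_date"


@dataclasses.dataclass(frozen=True)
class TTORecord:
    report_id: str
    ingredient: str
    event_group: Union[int, str]  # SMQ code or PT label
    days: int


@dataclasses.dataclass(frozen=True)
class Excluded:
    report_id: str
    reason: ExclusionReason


def compute_tto(
    report: SafetyReport,
    ingredient: str,
    event_predicate: EventPredicate,
    event_group: Union[int, str] = "",
) -> Union[TTORecord, Excluded, None]:
    """Time to onset for one report and ingredient, or the exclusion.

    Returns None when the report is out of scope (does not carry the
    ingredient or the event); otherwise a :class:`TTORecord` with
    ``days = event_date - earliest day-precision start date`` among the
    matching drug entries, or an :class:`Excluded` with the reason.
    Same-day onset (0 days) is kept; only start-after-onset is aberrant.
    """
    entries = [d for d in report.drugs if d.ingredient == ingredient]
    if not entries or not event_predicate(report):
        return None
    if report.event_date is None:
        return Excluded(report.report_id, ExclusionReason.MISSING_EVENT)
    starts = [d.start_date for d in entries if d.start_date is not None]
    if not starts:
        return Excluded(report.report_id, ExclusionReason.MISSING_START)
    day_starts = [s for s in starts if s.is_day]
    if not day_starts or not report.event_date.is_day:
        return Excluded(report.report_id, ExclusionReason.PARTIAL_DATE)
    start = min(day_starts, key=lambda s: s.date)  # first exposure
    days = (report.event_date.date - start.date).days
    if days < 0:
        return Excluded(report.report_id, ExclusionReason.NEGATIVE_INTERVAL)
    return TTORecord(report.report_id, ingredient, event_group, days)


@dataclasses.dataclass
class TTOSummary:
    n: int
    median: float
    q1: float
    q3: float
    pct_30d: float  # percent of records with days <= 30, 1 dp
    pct_90d: float
    exclusions: dict[str, int] = dataclasses.field(default_factory=dict)


def summarize_tto(
    records: Sequence[TTORecord],
    exclusions: Sequence[Excluded] = (),
) -> TTOSummary:
    """Median/IQR (type-7) and 30/90-day cumulative onset proportions."""
    if not records:
        raise ValueError("cannot summarize zero time-to-onset records")
    days = np.array([r.days for r in records], dtype=float)
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # linear = type 7
    counts: dict[str, int] = {}
    for e in exclusions:
        counts[e.reason.value] = counts.get(e.reason.value, 0) + 1
    return TTOSummary(
        n=len(records),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        pct_30d=round(float(np.mean(days <= 30)) * 100, 1),
        pct_90d=round(float(np.mean(days <= 90)) * 100, 1),
        exclusions=counts,
    )


def collect_tto(
    reports: Sequence[SafetyReport],
    ingredients: set[str],
    event_predicate: EventPredicate,
    event_group: Union[int, str] = "",
) -> tuple[list[TTORecord], list[Excluded]]:
    """Compute TTO for every report x matching ingredient.

    One record per (report, ingredient) pair so that agent-level and
    class-level summaries both fall out of the same records.
    """
    included: list[TTORecord] = []
    excluded: list[Excluded] = []
    for r in reports:
        for ing in sorted(ingredients & {d.ingredient for d in r.drugs if d.ingredient}):
            res = compute_tto(r, ing, event_predicate, event_group)
            if isinstance(res, TTORecord):
                included.append(res)
            elif isinstance(res, Excluded):
                excluded.append(res)
    return included, excluded
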