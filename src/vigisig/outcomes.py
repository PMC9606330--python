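"""Outcome-severity tabulation.

Each report may carry several outcome codes; by default one category is
assigned per report by severity precedence (death > life-threatening >
hospitalization > disability > congenital anomaly > other serious), so
category percentages partition the reports that have any outcome.  The
combined death + life-threatening percentage is the headline severity
metric.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import pandas as pd

from .model import Outcome, OUTCOME_SEVERITY, SafetyReport


def worst_outcome(report: SafetyReport) -> Optional[Outcome]:
    """Most severe outcome present, or None when the set is empty."""
    for outcome in OUTCOME_SEVERITY:
        if outcome in report.outcomes:
            return outcome
    return None


@dataclasses.dataclass
class OutcomeRow:
    group: str
    n: int  # reports in the group (denominator per `denominator` mode)
    percents: dict[str, float]  # per category, 1 dp; NaN when undefined
    death_lt_pct: float
    hospitalization_pct: float


def outcome_table(
    groups: dict[str, Sequence[SafetyReport]],
    denominator: str = "all",
    all_outcomes: bool = False,
) -> pd.DataFrame:
    """Per-group outcome percentages.

    ``groups`` maps a group label (event group or drug spec) to its
    reports.  ``denominator`` is ``"all"`` (all reports in the group,
    the default) or ``"with_outcome"`` (reports with >= 1 recorded
    outcome).  With ``all_outcomes`` every category a report carries is
    counted (sensitivity mode); otherwise one category per report by
    severity precedence.  Percentages are reported to 1 dp; an empty
    denominator yields NaN percentages.
    """
    if denominator not in ("all", "with_outcome"):
        raise ValueError(f"unknown denominator mode: {denominator!r}")
    rows = []
    for label, reports in groups.items():
        counts = {o.value: 0 for o in OUTCOME_SEVERITY}
        n_with = 0
        for r in reports:
            if r.outcomes:
                n_with += 1
            if all_outcomes:
                for o in r.outcomes:
                    counts[o.value] += 1
            else:
                w = worst_outcome(r)
                if w is not None:
                    counts[w.value] += 1
        denom = len(reports) if denominator == "all" else n_with
        if denom == 0:
            pct = {k: math.nan for k in counts}
        else:
            pct = {k: round(100.0 * v / denom, 1) for k, v in counts.items()}
        rows.append(
            {
                "group": label,
                "n": denom,
                **pct,
                "death_lt_pct": (
                    math.nan
                    if denom == 0
                    else round(
                        100.0
                        * (counts[Outcome.DEATH.value] + counts[Outcome.LIFE_THREATENING.value])
                        / denom,
                        1,
                    )
                ),
                "hospitalization_pct": pct[Outcome.HOSPITALIZATION.value],
            }
        )
    return pd.DataFrame(rows)
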