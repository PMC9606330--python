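"""Two-step cleaning of spontaneous reports.

Spontaneous-report databases contain versioned resubmissions (follow-ups
of the same case under one report id) and duplicates (the same case
submitted by different sources under different ids).  Cleaning is
two-step: keep only the last version per report id, then collapse
reports that agree on a six-field identity key (sex, age, reporter
country, receipt date, the multiset of reaction PTs, and the multiset of
verbatim drug names).  The key uses *verbatim* drug names because
cleaning precedes dictionary normalization in the pipeline.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

from .model import SafetyReport


@dataclasses.dataclass
class DedupLog:
    n_in: int = 0
    n_after_versions: int = 0
    n_after_duplicates: int = 0
    versions_removed: int = 0
    duplicates_removed: int = 0

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def keep_last_version(reports: list[SafetyReport]) -> list[SafetyReport]:
    """Keep the latest version of each report id.

    The survivor maximizes receipt date (partial dates compared by their
    earliest consistent calendar date; a missing date sorts first).  On a
    receipt-date tie the lexicographically largest report id wins, which
    is deterministic and matches the practice of version ids growing with
    resubmission.  Output is sorted by report id.
    """
    best: dict[str, SafetyReport] = {}
    for r in reports:
        cur = best.get(r.report_id)
        if cur is None or _version_key(r) > _version_key(cur):
            best[r.report_id] = r
    return [best[k] for k in sorted(best)]


def _version_key(r: SafetyReport):
    import datetime

    d = r.receipt_date.date if r.receipt_date else datetime.date.min
    return (d, r.report_id)


def duplicate_key(r: SafetyReport) -> tuple:
    """Six-field identity key; missing values compare equal to each other."""
    return (
        r.patient_sex.value,
        r.patient_age_years,
        r.country,
        r.receipt_date.isoformat() if r.receipt_date else None,
        tuple(sorted(r.reactions)),
        tuple(sorted(r.verbatim_drug_names())),
    )


def drop_field_duplicates(reports: list[SafetyReport]) -> list[SafetyReport]:
    """Among reports sharing the six-field key, keep the smallest report id.

    Expects input already reduced to one row per report id.  Output is
    sorted by report id.
    """
    best: dict[tuple, SafetyReport] = {}
    for r in reports:
        key = duplicate_key(r)
        cur = best.get(key)
        if cur is None or r.report_id < cur.report_id:
            best[key] = r
    return sorted(best.values(), key=lambda r: r.report_id)


def deduplicate(
    reports: list[SafetyReport],
) -> tuple[list[SafetyReport], DedupLog]:
    """Apply both cleaning steps and return survivors plus removal counts."""
    log = DedupLog(n_in=len(reports))
    after_versions = keep_last_version(reports)
    log.n_after_versions = len(after_versions)
    log.versions_removed = log.n_in - log.n_after_versions
    survivors = drop_field_duplicates(after_versions)
    log.n_after_duplicates = len(survivors)
    log.duplicates_removed = log.n_after_versions - log.n_after_duplicates
    return survivors, log
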