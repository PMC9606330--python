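"""Readers and writers for raw quarterly extracts and the CSV interchange.

Two dialects are supported:

* the public quarterly ASCII dialect: one '$'-delimited file per table
  role (DEMO, DRUG, REAC, OUTC, THER), linked by a primary-id column;
* a single-table RFC-4180 CSV interchange with list-valued columns
  serialized as ';'-joined tokens, which round-trips bit-exactly.

Every normalization decision that drops or alters a value is counted in
an :class:`IngestLog`; rows are never silently discarded.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence
from urllib.parse import quote, unquote

from .model import (
    AGE_MAX_YEARS,
    DrugEntry,
    DrugRole,
    Outcome,
    PartialDate,
    Precision,
    ReporterType,
    SafetyReport,
    Sex,
)


class IngestError(Exception):
    """File-level problem: missing mandatory column, duplicate header."""


class PartialDateError(ValueError):
    """Token does not match any accepted date shape."""


@dataclasses.dataclass
class IngestLog:
    """Counters for every lossy normalization decision during a read."""

    counters: Counter = dataclasses.field(default_factory=Counter)
    messages: list[str] = dataclasses.field(default_factory=list)

    def count(self, key: str, message: str | None = None) -> None:
        self.counters[key] += 1
        if message is not None:
            self.messages.append(message)


@dataclasses.dataclass
class IngestResult:
    """Reports plus the log of what was normalized away while reading."""

    reports: list[SafetyReport]
    log: IngestLog

    def __iter__(self) -> Iterator[SafetyReport]:
        return iter(self.reports)

    def __len__(self) -> int:
        return len(self.reports)


# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------

_DIGITS = re.compile(r"^\d{4}(\d{2})?(\d{2})?$")
_ISO = re.compile(r"^(\d{4})(?:-(\d{2}))?(?:-(\d{2}))?$")


def parse_partial_date(token: str) -> PartialDate:
    """Parse a 4/6/8-digit or ISO date token into a :class:`PartialDate`.

    Returns the earliest calendar date consistent with the token plus a
    precision tag.  Raises :class:`PartialDateError` for any other shape
    or an impossible calendar date (e.g. "20200230").
    """
    token = token.strip()
    if _DIGITS.match(token):
        year, month, day = token[:4], token[4:6] or None, token[6:8] or None
    else:
        m = _ISO.match(token)
        if not m:
            raise PartialDateError(f"unparseable date token: {token!r}")
        year, month, day = m.groups()
    try:
        if day is not None:
            return PartialDate(
                datetime.date(int(year), int(month), int(day)), Precision.DAY
            )
        if month is not None:
            return PartialDate(datetime.date(int(year), int(month), 1), Precision.MONTH)
        return PartialDate(datetime.date(int(year), 1, 1), Precision.YEAR)
    except ValueError as exc:  # impossible calendar date
        raise PartialDateError(f"invalid calendar date: {token!r}") from exc


def _maybe_date(token: str, log: IngestLog, field: str) -> Optional[PartialDate]:
    if not token or not token.strip():
        return None
    try:
        return parse_partial_date(token)
    except PartialDateError:
        log.count(f"bad_{field}", f"unparseable {field}: {token!r}")
        return None


# ---------------------------------------------------------------------------
# field token maps
# ---------------------------------------------------------------------------

#: Age unit conversion to years.  DEC = decades, HR uses the mean
#: Gregorian year of 8766 hours.
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "DEC": 10.0,
    "HR": 1.0 / 8766.0,
}

_SEX_TOKENS = {
    "M": Sex.MALE,
    "MALE": Sex.MALE,
    "F": Sex.FEMALE,
    "FEMALE": Sex.FEMALE,
    "UNK": Sex.UNKNOWN,
    "UNKNOWN": Sex.UNKNOWN,
    "": Sex.UNKNOWN,
}

_ROLE_TOKENS = {
    "PS": DrugRole.PRIMARY_SUSPECT,
    "SS": DrugRole.SECONDARY_SUSPECT,
    "C": DrugRole.CONCOMITANT,
    "I": DrugRole.INTERACTING,
}

_OUTCOME_TOKENS = {
    "DE": Outcome.DEATH,
    "LT": Outcome.LIFE_THREATENING,
    "HO": Outcome.HOSPITALIZATION,
    "DS": Outcome.DISABILITY,
    "CA": Outcome.CONGENITAL_ANOMALY,
    "OT": Outcome.OTHER_SERIOUS,
}

#: Occupation codes mapped to reporter type: physician, pharmacist,
#: other health professional vs consumer / lawyer.
_REPORTER_TOKENS = {
    "MD": ReporterType.HEALTH_PROFESSIONAL,
    "PH": ReporterType.HEALTH_PROFESSIONAL,
    "HP": ReporterType.HEALTH_PROFESSIONAL,
    "RN": ReporterType.HEALTH_PROFESSIONAL,
    "OT": ReporterType.HEALTH_PROFESSIONAL,
    "CN": ReporterType.NON_HEALTH_PROFESSIONAL,
    "LW": ReporterType.NON_HEALTH_PROFESSIONAL,
}


def convert_age(value: str, unit: str, log: IngestLog) -> Optional[float]:
    """Convert a reported age value/unit pair to years; out-of-range or
    unknown-unit ages are logged and returned missing."""
    value = (value or "").strip()
    unit = (unit or "YR").strip().upper() or "YR"
    if not value:
        return None
    try:
        raw = float(value)
    except ValueError:
        log.count("bad_age_value", f"non-numeric age: {value!r}")
        return None
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        log.count("unknown_age_unit", f"unknown age unit: {unit!r}")
        return None
    years = raw * factor
    if not (0.0 <= years <= AGE_MAX_YEARS):
        log.count("age_out_of_range", f"age out of range: {years:.2f} years")
        return None
    return years


def parse_sex(token: str) -> Sex:
    return _SEX_TOKENS.get((token or "").strip().upper(), Sex.UNKNOWN)


def parse_reporter(token: str) -> ReporterType:
    token = (token or "").strip().upper()
    if not token:
        return ReporterType.UNKNOWN
    return _REPORTER_TOKENS.get(token, ReporterType.UNKNOWN)


# ---------------------------------------------------------------------------
# '$'-delimited quarterly ASCII dialect
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = {
    "demo": ["primaryid"],
    "drug": ["primaryid", "drugname"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
}


def _read_dollar_file(path: Path, role: str, log: IngestLog) -> list[dict[str, str]]:
    """Read one '$'-delimited table with UTF-8 then latin-1 fallback."""
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError:
        text = path.read_text(encoding="latin-1")
        log.count("latin1_fallback", f"{path.name}: decoded as latin-1")
    lines = text.splitlines()
    if not lines:
        raise IngestError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split("$")]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise IngestError(f"{path}: duplicate header column(s) {dupes}")
    for col in MANDATORY_COLUMNS[role]:
        if col not in header:
            raise IngestError(f"{path}: missing mandatory column {col!r}")
    rows: list[dict[str, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("$")
        if len(parts) != len(header):
            log.count("malformed_row", f"{path.name}:{lineno}: field count mismatch")
            continue
        rows.append(dict(zip(header, parts)))
    return rows


def read_faers_ascii(
    paths: Mapping[str, str | Path], quarter: str | None = None
) -> IngestResult:
    """Read one quarterly set of '$'-delimited files into safety reports.

    ``paths`` maps table roles (``demo``/``drug``/``reac``/``outc``/``ther``)
    to file paths; ``demo`` is mandatory, the rest optional.  Child rows
    are attached to their case by the primary-id join.  ``quarter`` is a
    label recorded in the log only.
    """
    log = IngestLog()
    paths = {k.lower(): Path(v) for k, v in paths.items()}
    if "demo" not in paths:
        raise IngestError("a DEMO file is required")
    for role, path in paths.items():
        if role not in MANDATORY_COLUMNS:
            raise IngestError(f"unknown table role {role!r}")
        if not path.exists():
            raise IngestError(f"{path}: file not found")

    demo_rows = _read_dollar_file(paths["demo"], "demo", log)
    child: dict[str, list[dict[str, str]]] = {}
    for role in ("drug", "reac", "outc", "ther"):
        child[role] = (
            _read_dollar_file(paths[role], role, log) if role in paths else []
        )

    by_id: dict[str, dict[str, list[dict[str, str]]]] = {}
    for role in ("drug", "reac", "outc", "ther"):
        for row in child[role]:
            by_id.setdefault(row["primaryid"].strip(), {}).setdefault(role, []).append(
                row
            )

    n_cases = 0
    reports: list[SafetyReport] = []
    for row in demo_rows:
        n_cases += 1
        pid = row["primaryid"].strip()
        if not pid:
            log.count("missing_primaryid", "DEMO row without primaryid")
            continue
        kids = by_id.get(pid, {})
        receipt = _maybe_date(row.get("receiptdate", ""), log, "receiptdate")
        event = _maybe_date(row.get("event_dt", ""), log, "event_dt")
        # therapy start dates keyed by drug sequence number
        ther_starts: dict[str, Optional[PartialDate]] = {}
        for trow in kids.get("ther", []):
            ther_starts[trow.get("dsg_drug_seq", "").strip()] = _maybe_date(
                trow.get("start_dt", ""), log, "start_dt"
            )
        drugs: list[DrugEntry] = []
        for drow in kids.get("drug", []):
            name = (drow.get("drugname") or "").strip()
            if not name:
                log.count("empty_drugname", f"case {pid}: empty drug name")
                continue
            seq = (drow.get("drug_seq") or "").strip()
            start = _maybe_date(drow.get("start_dt", ""), log, "start_dt")
            if start is None and seq in ther_starts:
                start = ther_starts[seq]
            drugs.append(
                DrugEntry(
                    verbatim_name=name,
                    role=_ROLE_TOKENS.get(
                        (drow.get("role_cod") or "").strip().upper(), DrugRole.UNKNOWN
                    ),
                    start_date=start,
                )
            )
        reactions = [
            (rrow.get("pt") or "").strip()
            for rrow in kids.get("reac", [])
            if (rrow.get("pt") or "").strip()
        ]
        if not reactions:
            log.count("no_reactions", f"case {pid}: no reaction rows")
        outcomes = {
            _OUTCOME_TOKENS[tok]
            for orow in kids.get("outc", [])
            if (tok := (orow.get("outc_cod") or "").strip().upper())
            in _OUTCOME_TOKENS
        }
        reports.append(
            SafetyReport(
                report_id=pid,
                case_id=(row.get("caseid") or pid).strip() or pid,
                receipt_date=receipt,
                patient_age_years=convert_age(
                    row.get("age", ""), row.get("age_cod", ""), log
                ),
                patient_sex=parse_sex(row.get("sex", "")),
                reporter_type=parse_reporter(row.get("occp_cod", "")),
                country=(row.get("reporter_country") or "unknown").strip()
                or "unknown",
                event_date=event,
                drugs=drugs,
                reactions=reactions,
                outcomes=outcomes,
                report_year=receipt.date.year if receipt else None,
            )
        )
    log.counters["n_cases_in"] = n_cases
    log.counters["n_reports_out"] = len(reports)
    log.counters["n_rejected"] = n_cases - len(reports)
    if quarter:
        log.messages.append(f"quarter {quarter}: {len(reports)} reports")
    return IngestResult(reports, log)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

INTERCHANGE_COLUMNS = [
    "report_id",
    "case_id",
    "receipt_date",
    "patient_age_years",
    "patient_sex",
    "reporter_type",
    "country",
    "event_date",
    "report_year",
    "reactions",
    "outcomes",
    "drugs",
]

_LIST_SEP = ";"
_FIELD_SEP = "|"


def _encode_token(text: str) -> str:
    # verbatim names are free text: protect the list/field separators
    return quote(text, safe=" .,()-")


def _encode_drug(d: DrugEntry) -> str:
    return _FIELD_SEP.join(
        [
            _encode_token(d.verbatim_name),
            d.role.value,
            d.start_date.isoformat() if d.start_date else "",
            _encode_token(d.ingredient) if d.ingredient else "",
            d.drug_class.value if d.drug_class else "",
        ]
    )


def _decode_drug(token: str, log: IngestLog) -> DrugEntry:
    name, role, start, ingredient, cls = token.split(_FIELD_SEP)
    start_pd = _maybe_date(start, log, "start_date") if start else None
    from .model import DrugClass  # local to avoid cycle noise at import

    return DrugEntry(
        verbatim_name=unquote(name),
        role=DrugRole(role),
        start_date=start_pd,
        ingredient=unquote(ingredient) if ingredient else None,
        drug_class=DrugClass(cls) if cls else None,
    )


def write_interchange_csv(reports: Iterable[SafetyReport], path: str | Path) -> None:
    """Write reports to the single-table CSV interchange format."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(INTERCHANGE_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    r.report_id,
                    r.case_id,
                    r.receipt_date.isoformat() if r.receipt_date else "",
                    repr(r.patient_age_years) if r.patient_age_years is not None else "",
                    r.patient_sex.value,
                    r.reporter_type.value,
                    r.country,
                    r.event_date.isoformat() if r.event_date else "",
                    r.report_year if r.report_year is not None else "",
                    _LIST_SEP.join(_encode_token(pt) for pt in r.reactions),
                    _LIST_SEP.join(sorted(o.value for o in r.outcomes)),
                    _LIST_SEP.join(_encode_drug(d) for d in r.drugs),
                ]
            )


def read_interchange_csv(path: str | Path) -> IngestResult:
    """Read the CSV interchange format back into safety reports.

    Malformed date strings set the field missing and increment a warning
    counter; they never raise.
    """
    log = IngestLog()
    reports: list[SafetyReport] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in INTERCHANGE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise IngestError(f"{path}: missing interchange column(s) {missing}")
        for row in reader:
            receipt = _maybe_date(row["receipt_date"], log, "receipt_date")
            event = _maybe_date(row["event_date"], log, "event_date")
            reports.append(
                SafetyReport(
                    report_id=row["report_id"],
                    case_id=row["case_id"],
                    receipt_date=receipt,
                    patient_age_years=(
                        float(row["patient_age_years"])
                        if row["patient_age_years"]
                        else None
                    ),
                    patient_sex=parse_sex(row["patient_sex"]),
                    reporter_type=(
                        ReporterType(row["reporter_type"])
                        if row["reporter_type"]
                        else ReporterType.UNKNOWN
                    ),
                    country=row["country"] or "unknown",
                    event_date=event,
                    drugs=[
                        _decode_drug(tok, log)
                        for tok in row["drugs"].split(_LIST_SEP)
                        if tok
                    ],
                    reactions=[
                        unquote(tok)
                        for tok in row["reactions"].split(_LIST_SEP)
                        if tok
                    ],
                    outcomes={
                        Outcome(tok)
                        for tok in row["outcomes"].split(_LIST_SEP)
                        if tok
                    },
                    report_year=(
                        int(row["report_year"]) if row["report_year"] else None
                    ),
                )
            )
    log.counters["n_reports_out"] = len(reports)
    return IngestResult(reports, log)
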