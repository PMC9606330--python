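"""Normalized domain model for spontaneous adverse-event reports.

The model is dialect-agnostic: the same :class:`SafetyReport` is produced
whether the raw input is a '$'-delimited quarterly extract or the
normalized CSV interchange format.  Field semantics follow the public
FAERS vocabulary (safetyreportid, receiptdate, reaction MedDRA PT,
medicinal product, ...) but no particular file layout is assumed here.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
from typing import Optional


class Precision(str, enum.Enum):
    """Precision of a possibly partial calendar date."""

    YEAR = "year"
    MONTH = "month"
    DAY = "day"


@dataclasses.dataclass(frozen=True)
class PartialDate:
    """A calendar date that may be known only to year or month precision.

    ``date`` is the *earliest* calendar date consistent with the reported
    token (e.g. "202003" -> 2020-03-01 at month precision), which gives a
    total order for version comparisons while keeping the original
    precision available for stages that require full dates.
    """

    date: datetime.date
    precision: Precision = Precision.DAY

    def isoformat(self) -> str:
        if self.precision is Precision.YEAR:
            return f"{self.date.year:04d}"
        if self.precision is Precision.MONTH:
            return f"{self.date.year:04d}-{self.date.month:02d}"
        return self.date.isoformat()

    @property
    def is_day(self) -> bool:
        return self.precision is Precision.DAY

    def __lt__(self, other: "PartialDate") -> bool:
        return self.date < other.date


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class ReporterType(str, enum.Enum):
    HEALTH_PROFESSIONAL = "health_professional"
    NON_HEALTH_PROFESSIONAL = "non_health_professional"
    UNKNOWN = "unknown"


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"
    UNKNOWN = "unknown"


#: Roles counted as drug exposure by default in disproportionality panels.
SUSPECT_ROLES = frozenset({DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT})
ALL_ROLES = frozenset(DrugRole)


class DrugClass(str, enum.Enum):
    ANTI_VEGF_MAB = "anti_VEGF_mAb"
    ANTI_VEGFR_MAB = "anti_VEGFR_mAb"
    VEGF_TRAP = "VEGF_trap"
    TKI = "TKI"
    OTHER_ANTIANGIOGENIC = "other_antiangiogenic"
    NON_TARGET = "non_target"


#: Classes forming the intravenous monoclonal-antibody superclass
#: (anti-VEGF mAb, anti-VEGFR mAb and the soluble decoy receptor), as
#: opposed to the oral small-molecule TKI superclass.
MAB_SUPERCLASS = frozenset(
    {DrugClass.ANTI_VEGF_MAB, DrugClass.ANTI_VEGFR_MAB, DrugClass.VEGF_TRAP}
)
TKI_SUPERCLASS = frozenset({DrugClass.TKI})


class Outcome(str, enum.Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    OTHER_SERIOUS = "other_serious"


#: Severity precedence, most severe first.
OUTCOME_SEVERITY: tuple[Outcome, ...] = (
    Outcome.DEATH,
    Outcome.LIFE_THREATENING,
    Outcome.HOSPITALIZATION,
    Outcome.DISABILITY,
    Outcome.CONGENITAL_ANOMALY,
    Outcome.OTHER_SERIOUS,
)


@dataclasses.dataclass
class DrugEntry:
    """One drug record on a report; the verbatim product name is free text."""

    verbatim_name: str
    role: DrugRole = DrugRole.UNKNOWN
    start_date: Optional[PartialDate] = None
    ingredient: Optional[str] = None  # filled by the vocab stage
    drug_class: Optional[DrugClass] = None  # filled by the vocab stage

    def __post_init__(self) -> None:
        self.verbatim_name = self.verbatim_name.strip()
        if not self.verbatim_name:
            raise ValueError("DrugEntry.verbatim_name must be non-empty")


@dataclasses.dataclass
class SafetyReport:
    """One normalized spontaneous report (one version of one case)."""

    report_id: str
    case_id: str = ""
    receipt_date: Optional[PartialDate] = None
    patient_age_years: Optional[float] = None
    patient_sex: Sex = Sex.UNKNOWN
    reporter_type: ReporterType = ReporterType.UNKNOWN
    country: str = "unknown"
    event_date: Optional[PartialDate] = None
    drugs: list[DrugEntry] = dataclasses.field(default_factory=list)
    reactions: list[str] = dataclasses.field(default_factory=list)
    outcomes: set[Outcome] = dataclasses.field(default_factory=set)
    report_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("SafetyReport.report_id must be non-empty")
        if not self.case_id:
            self.case_id = self.report_id

    # --- convenience views used by downstream stages -------------------

    def ingredients(self, roles: frozenset[DrugRole] = ALL_ROLES) -> set[str]:
        """Mapped ingredients on this report, restricted to ``roles``."""
        return {
            d.ingredient
            for d in self.drugs
            if d.ingredient is not None and d.role in roles
        }

    def verbatim_drug_names(self) -> list[str]:
        return [d.verbatim_name for d in self.drugs]


#: Age bound in years; values outside after unit conversion are treated as
#: data errors and set missing (logged by the ingest stage).
AGE_MAX_YEARS = 120.0
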