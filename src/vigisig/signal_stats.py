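"""Shrinkage-based disproportionality statistics for report-level 2x2 tables.

For a target drug set and target event definition, every deduplicated
report falls in exactly one cell of a two-by-two contingency table::

                        target event    other events
    target drug            a                b          N_drug  = a + b
    other drugs            c                d
                       N_event = a + c              N_total = a+b+c+d

The expected count under independence is ``N_expected = N_drug * N_event
/ N_total``.  Both disproportionality measures derive from the same
shrinkage-transformed observed/expected ratio

    ratio = (N_observed + k) / (N_expected + k),    k = 0.5

with the reporting ratio ROR = ratio and the information component
IC = log2(ratio).  The 95% credibility bounds of IC use the closed-form
approximations

    IC025 = IC - 3.3 (N+0.5)^-1/2 - 2   (N+0.5)^-3/2
    IC975 = IC + 2.4 (N+0.5)^-1/2 - 0.5 (N+0.5)^-3/2

(N = N_observed).  The ROR interval uses the classical Woolf standard
error sqrt(1/a + 1/b + 1/c + 1/d) around a selectable point estimate
(the shrunk ratio by default, the classical odds ratio ad/bc as an
alternative).  A drug-event pair is flagged as a signal when it has at
least ``min_reports`` reports and ROR025 > 1 or IC025 > 0.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Optional, Sequence

from .model import ALL_ROLES, DrugRole, SafetyReport, SUSPECT_ROLES
from .vocab import DrugArchive, SMQDefinition, canonicalize, map_pt_to_smqs, resolve_drug_spec


class SignalError(Exception):
    pass


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Report counts a/b/c/d of one drug-set x event-set analysis."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise SignalError("contingency cells must be non-negative")
        if self.n_total < 1:
            raise SignalError("contingency table must contain at least one report")

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_expected(self) -> float:
        return self.n_drug * self.n_event / self.n_total


@dataclasses.dataclass(frozen=True)
class ShrinkageConfig:
    """Constants of the shrinkage transformation and the signal rule."""

    shrinkage_k: float = 0.5
    z: float = 1.96
    ic_low_c1: float = 3.3
    ic_low_c2: float = 2.0
    ic_high_c1: float = 2.4
    ic_high_c2: float = 0.5
    min_reports: int = 3

    def __post_init__(self) -> None:
        if self.shrinkage_k < 0:
            raise SignalError("shrinkage_k must be >= 0")
        if self.min_reports < 1:
            raise SignalError("min_reports must be >= 1")


DEFAULT_CONFIG = ShrinkageConfig()


@dataclasses.dataclass
class SignalEstimate:
    """Shrunk ROR/IC with interval bounds and the signal flag for one cell."""

    name: str
    n_observed: int
    ror_shrunk: float
    ror_ci_low: Optional[float]
    ror_ci_high: Optional[float]
    ic: float
    ic_low: float
    ic_high: float
    is_signal: bool
    n_expected: float = math.nan


# ---------------------------------------------------------------------------
# building tables
# ---------------------------------------------------------------------------

EventPredicate = Callable[[SafetyReport], bool]


def pt_predicate(pts: Iterable[str]) -> EventPredicate:
    """Event predicate: the report mentions any of the given PTs."""
    canon = {canonicalize(p) for p in pts}

    def pred(report: SafetyReport) -> bool:
        return any(canonicalize(pt) in canon for pt in report.reactions)

    return pred


def smq_predicate(smq_code: int, defs: dict[int, SMQDefinition]) -> EventPredicate:
    """Event predicate: any reaction PT belongs to the SMQ (narrow scope,
    including membership inherited from sub-SMQs)."""
    if smq_code not in defs:
        raise SignalError(f"unknown SMQ code: {smq_code}")

    def pred(report: SafetyReport) -> bool:
        return any(smq_code in map_pt_to_smqs(pt, defs) for pt in report.reactions)

    return pred


def build_contingency(
    reports: Sequence[SafetyReport],
    target_drugs: set[str],
    target_events: EventPredicate,
    role_filter: frozenset[DrugRole] = SUSPECT_ROLES,
) -> ContingencyTable:
    """Classify each report into exactly one cell of the 2x2 table.

    A report is drug-exposed if it carries >= 1 target ingredient whose
    drug entry passes the role filter, and event-positive if >= 1 of its
    reactions satisfies the event predicate.  The counting unit is the
    report: repeated PTs or drugs within a report count once.
    """
    if not reports:
        raise SignalError("cannot build a contingency table from zero reports")
    a = b = c = d = 0
    for r in reports:
        exposed = bool(r.ingredients(role_filter) & target_drugs)
        event = target_events(r)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def shrunk_ratio(table: ContingencyTable, cfg: ShrinkageConfig = DEFAULT_CONFIG) -> float:
    """(N_observed + k) / (N_expected + k); defined even at a = 0."""
    return (table.a + cfg.shrinkage_k) / (table.n_expected + cfg.shrinkage_k)


def ic_stats(
    n_observed: int, ratio: float, cfg: ShrinkageConfig = DEFAULT_CONFIG
) -> tuple[float, float, float]:
    """Information component and its 95% bounds from the shrunk ratio."""
    if ratio <= 0:
        raise SignalError("shrunk ratio must be positive")
    ic = math.log2(ratio)
    half = (n_observed + 0.5) ** -0.5
    three_half = (n_observed + 0.5) ** -1.5
    ic_low = ic - cfg.ic_low_c1 * half - cfg.ic_low_c2 * three_half
    ic_high = ic + cfg.ic_high_c1 * half - cfg.ic_high_c2 * three_half
    return ic, ic_low, ic_high


def ror_ci(
    table: ContingencyTable,
    cfg: ShrinkageConfig = DEFAULT_CONFIG,
    point: str = "shrunk",
) -> tuple[Optional[float], Optional[float]]:
    """95% CI exp(ln(point) -/+ z*sqrt(1/a+1/b+1/c+1/d)).

    ``point`` is ``"shrunk"`` (the shrunk observed/expected ratio) or
    ``"classical"`` (the odds ratio ad/bc).  Any zero cell leaves the
    standard error undefined: bounds are returned as None, never
    substituted.
    """
    if min(table.a, table.b, table.c, table.d) < 1:
        return None, None
    if point == "shrunk":
        center = shrunk_ratio(table, cfg)
    elif point == "classical":
        center = (table.a * table.d) / (table.b * table.c)
    else:
        raise SignalError(f"unknown ROR point estimate: {point!r}")
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return center * math.exp(-cfg.z * se), center * math.exp(cfg.z * se)


def detect_signal(est: SignalEstimate, cfg: ShrinkageConfig = DEFAULT_CONFIG) -> bool:
    """Signal rule: >= min_reports and (ROR025 > 1 or IC025 > 0).

    An undefined ROR025 (zero cell) does not satisfy its clause.
    """
    if est.n_observed < cfg.min_reports:
        return False
    ror_clause = est.ror_ci_low is not None and est.ror_ci_low > 1.0
    return ror_clause or est.ic_low > 0.0


def estimate_cell(
    name: str,
    table: ContingencyTable,
    cfg: ShrinkageConfig = DEFAULT_CONFIG,
    ror_point: str = "shrunk",
) -> SignalEstimate:
    """Full estimate for one analysis cell."""
    ratio = shrunk_ratio(table, cfg)
    ic, ic_low, ic_high = ic_stats(table.a, ratio, cfg)
    low, high = ror_ci(table, cfg, point=ror_point)
    est = SignalEstimate(
        name=name,
        n_observed=table.a,
        ror_shrunk=ratio,
        ror_ci_low=low,
        ror_ci_high=high,
        ic=ic,
        ic_low=ic_low,
        ic_high=ic_high,
        is_signal=False,
        n_expected=table.n_expected,
    )
    est.is_signal = detect_signal(est, cfg)
    return est


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Analysis:
    """One row of a panel: a named drug spec x event spec pair.

    ``drug_spec`` as accepted by :func:`vigisig.vocab.resolve_drug_spec`;
    ``event_spec`` is ``("smq", code)`` or ``("pt", name)`` or
    ``("pts", iterable-of-names)``.
    """

    name: str
    drug_spec: str
    event_spec: tuple


def _resolve_event_spec(
    spec: tuple, defs: Optional[dict[int, SMQDefinition]]
) -> EventPredicate:
    kind = spec[0]
    if kind == "smq":
        if defs is None:
            raise SignalError("SMQ event spec requires SMQ definitions")
        return smq_predicate(int(spec[1]), defs)
    if kind == "pt":
        return pt_predicate([spec[1]])
    if kind == "pts":
        return pt_predicate(spec[1])
    raise SignalError(f"unknown event spec: {spec!r}")


def run_panel(
    reports: Sequence[SafetyReport],
    analyses: Sequence[Analysis],
    archive: DrugArchive,
    smq_defs: Optional[dict[int, SMQDefinition]] = None,
    cfg: ShrinkageConfig = DEFAULT_CONFIG,
    role_filter: frozenset[DrugRole] = SUSPECT_ROLES,
) -> list[SignalEstimate]:
    """One estimate per analysis, in the given (deterministic) order.

    Report membership is precomputed per ingredient and per reaction so
    that large panels over large report sets stay linear in the data.
    """
    if not reports:
        raise SignalError("cannot run a panel on zero reports")
    n = len(reports)
    # index: ingredient -> report indices (role-filtered), canonical PT -> indices
    by_ingredient: dict[str, set[int]] = {}
    by_pt: dict[str, set[int]] = {}
    for i, r in enumerate(reports):
        for ing in r.ingredients(role_filter):
            by_ingredient.setdefault(ing, set()).add(i)
        for pt in r.reactions:
            by_pt.setdefault(canonicalize(pt), set()).add(i)

    def event_indices(spec: tuple) -> set[int]:
        kind = spec[0]
        if kind == "pt":
            return set(by_pt.get(canonicalize(spec[1]), set()))
        if kind == "pts":
            out: set[int] = set()
            for p in spec[1]:
                out |= by_pt.get(canonicalize(p), set())
            return out
        if kind == "smq":
            if smq_defs is None:
                raise SignalError("SMQ event spec requires SMQ definitions")
            code = int(spec[1])
            if code not in smq_defs:
                raise SignalError(f"unknown SMQ code: {code}")
            out = set()
            for pt_canon, idx in by_pt.items():
                if code in map_pt_to_smqs(pt_canon, smq_defs):
                    out |= idx
            return out
        raise SignalError(f"unknown event spec: {spec!r}")

    results: list[SignalEstimate] = []
    for an in analyses:
        drugs = resolve_drug_spec(an.drug_spec, archive)
        exposed: set[int] = set()
        for ing in drugs:
            exposed |= by_ingredient.get(ing, set())
        events = event_indices(an.event_spec)
        a = len(exposed & events)
        b = len(exposed) - a
        c = len(events) - a
        d = n - a - b - c
        results.append(estimate_cell(an.name, ContingencyTable(a, b, c, d), cfg))
    return results


def pt_spectrum(
    reports: Sequence[SafetyReport],
    drug_spec: str,
    archive: DrugArchive,
    cfg: ShrinkageConfig = DEFAULT_CONFIG,
    role_filter: frozenset[DrugRole] = SUSPECT_ROLES,
) -> list[SignalEstimate]:
    """Per-PT spectrum: one estimate for every PT with n_observed >= 1
    among reports exposed to the drug spec, sorted by descending IC025
    then PT name."""
    drugs = resolve_drug_spec(drug_spec, archive)
    n = len(reports)
    if n == 0:
        raise SignalError("cannot run a spectrum on zero reports")
    exposed_idx: set[int] = set()
    by_pt: dict[str, set[int]] = {}
    display: dict[str, str] = {}
    for i, r in enumerate(reports):
        if r.ingredients(role_filter) & drugs:
            exposed_idx.add(i)
        for pt in r.reactions:
            canon = canonicalize(pt)
            by_pt.setdefault(canon, set()).add(i)
            display.setdefault(canon, pt)
    out: list[SignalEstimate] = []
    for canon, idx in by_pt.items():
        a = len(idx & exposed_idx)
        if a < 1:
            continue
        b = len(exposed_idx) - a
        c = len(idx) - a
        d = n - a - b - c
        out.append(estimate_cell(display[canon], ContingencyTable(a, b, c, d), cfg))
    out.sort(key=lambda e: (-e.ic_low, e.name))
    return out


# ---------------------------------------------------------------------------
# presentation rounding
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (publication-style), e.g. 0.125 -> 0.13."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
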