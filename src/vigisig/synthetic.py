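"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a FAERS-style report stream: patient
demographics, one or two drugs per report with roles, verbatim product
names drawn from synonym lists (optionally with injected typos), per-PT
reaction sampling with planted drug-event reporting-ratio multipliers
(lambda), log-normal time-to-onset realizations, outcome codes,
duplicate submissions under fresh report ids, and versioned
resubmissions under the same report id.  A JSON-serializable ground
truth sidecar records what was planted so every pipeline stage can be
verified offline.

Event sampling: each reaction PT fires independently; a report whose
drugs elevate the PT fires at ``base_rate * max(lambda(drug, pt) over
the report's drugs)`` — the max (rather than a product) keeps each
drug-event pair interpretable on its own — while reports with no
elevating drug fire at a slightly deflated rate chosen so the marginal
PT rate stays at ``base_rate``.  The deflation makes the planted
multiplier identifiable: lambda is then exactly the report-level
observed/expected reporting ratio that the pipeline estimates, rather
than that ratio diluted by the exposed reports' own contribution to the
margin.  Under lambda = 1 everywhere no deflation occurs and drug and
event indicators are independent.

What this generator does *not* emulate: secular reporting trends,
stimulated reporting and notoriety bias, correlated multi-event
syndromes, or free-text noise beyond single-character typos.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
import string
from typing import Optional, Sequence

import numpy as np

from .dedup import duplicate_key
from .model import (
    DrugClass,
    DrugEntry,
    DrugRole,
    Outcome,
    PartialDate,
    Precision,
    ReporterType,
    SafetyReport,
    Sex,
)
from .signal_stats import Analysis, DEFAULT_CONFIG, run_panel
from .tto import collect_tto, summarize_tto
from .vocab import ArchiveRow, DrugArchive, map_reports
from .signal_stats import pt_predicate


class SimConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DrugSpec:
    ingredient: str
    drug_class: DrugClass
    synonyms: tuple[str, ...]
    marginal_prob: float


@dataclasses.dataclass(frozen=True)
class EventSpec:
    pt: str
    smq_codes: tuple[int, ...]
    base_rate: float


@dataclasses.dataclass
class SimConfig:
    """Full parameterization of the generator.

    Defaults emulate a desk-scale angiogenesis-inhibitor study: a
    handful of VEGF(R)-pathway agents against a background drug,
    cardiovascular PTs grouped under their SMQ codes next to
    non-cardiovascular background PTs, hypertension planted with an
    elevated reporting ratio and the short onset profile (median 23
    days) and thrombotic events with the long one (median 51 days).
    """

    n_reports: int = 100_000
    seed: int = 0
    drug_catalog: tuple[DrugSpec, ...] = (
        DrugSpec("bevacizumab", DrugClass.ANTI_VEGF_MAB, ("bevacizumab", "avastin"), 0.03),
        DrugSpec("aflibercept", DrugClass.VEGF_TRAP, ("aflibercept", "zaltrap"), 0.01),
        DrugSpec("sunitinib", DrugClass.TKI, ("sunitinib", "sutent", "SU11248"), 0.02),
        DrugSpec("lenvatinib", DrugClass.TKI, ("lenvatinib", "lenvima"), 0.02),
        DrugSpec("sorafenib", DrugClass.TKI, ("sorafenib", "nexavar"), 0.02),
        DrugSpec("metformin", DrugClass.NON_TARGET, ("metformin", "glucophage"), 0.45),
        DrugSpec("atorvastatin", DrugClass.NON_TARGET, ("atorvastatin", "lipitor"), 0.45),
    )
    event_catalog: tuple[EventSpec, ...] = (
        EventSpec("Hypertension", (20000147,), 0.02),
        EventSpec("Blood pressure increased", (20000147,), 0.01),
        EventSpec("Pulmonary embolism", (20000081, 20000084), 0.01),
        EventSpec("Cerebrovascular accident", (20000081, 20000082), 0.008),
        EventSpec("Cardiac failure", (20000004,), 0.01),
        EventSpec("Nausea", (), 0.06),
        EventSpec("Fatigue", (), 0.05),
        EventSpec("Diarrhoea", (), 0.04),
    )
    planted_lambda: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: {
            ("bevacizumab", "Hypertension"): 3.0,
            ("lenvatinib", "Blood pressure increased"): 4.0,
            ("bevacizumab", "Pulmonary embolism"): 2.0,
        }
    )
    dup_prob: float = 0.05
    version_prob: float = 0.05
    missing_start_prob: float = 0.25
    missing_event_prob: float = 0.15
    partial_date_prob: float = 0.10
    missing_age_prob: float = 0.05
    typo_prob: float = 0.02
    second_drug_prob: float = 0.30
    extra_outcome_prob: float = 0.10
    tto_lognormal: dict[tuple[str, str], tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            ("bevacizumab", "Hypertension"): (23.0, 1.0),
            ("lenvatinib", "Blood pressure increased"): (23.0, 1.0),
            ("bevacizumab", "Pulmonary embolism"): (51.0, 1.0),
        }
    )
    default_tto: tuple[float, float] = (60.0, 1.2)
    outcome_probs: dict[Outcome, float] = dataclasses.field(
        default_factory=lambda: {
            Outcome.DEATH: 0.12,
            Outcome.LIFE_THREATENING: 0.05,
            Outcome.HOSPITALIZATION: 0.30,
            Outcome.DISABILITY: 0.01,
            Outcome.CONGENITAL_ANOMALY: 0.001,
            Outcome.OTHER_SERIOUS: 0.25,
        }
    )
    sex_probs: tuple[float, float, float] = (0.44, 0.47, 0.09)  # male, female, unknown
    reporter_probs: tuple[float, float, float] = (0.60, 0.35, 0.05)  # hp, non-hp, unk
    countries: tuple[str, ...] = ("US", "JP", "FR", "DE", "CN")
    country_probs: tuple[float, ...] = (0.50, 0.15, 0.13, 0.12, 0.10)
    age_mean: float = 64.0
    age_sd: float = 12.0
    window_start: datetime.date = datetime.date(2014, 1, 1)
    window_end: datetime.date = datetime.date(2021, 12, 31)

    def validate(self) -> None:
        probs = [
            self.dup_prob,
            self.version_prob,
            self.missing_start_prob,
            self.missing_event_prob,
            self.partial_date_prob,
            self.missing_age_prob,
            self.typo_prob,
            self.second_drug_prob,
            self.extra_outcome_prob,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise SimConfigError("all probabilities must lie in [0, 1]")
        if self.n_reports < 1:
            raise SimConfigError("n_reports must be >= 1")
        if abs(sum(d.marginal_prob for d in self.drug_catalog) - 1.0) > 1e-9:
            raise SimConfigError("drug marginal probabilities must sum to 1")
        if sum(self.outcome_probs.values()) > 1.0 + 1e-9:
            raise SimConfigError("outcome probabilities must sum to <= 1")
        lam_max: dict[str, float] = {}
        for (ing, pt), lam in self.planted_lambda.items():
            if lam <= 0:
                raise SimConfigError("planted lambda must be positive")
            lam_max[pt] = max(lam_max.get(pt, 1.0), lam)
        for ev in self.event_catalog:
            if ev.base_rate * lam_max.get(ev.pt, 1.0) > 1.0:
                raise SimConfigError(
                    f"lambda * base_rate exceeds 1 for PT {ev.pt!r}"
                )


@dataclasses.dataclass
class SimOutput:
    reports: list[SafetyReport]  # pre-dedup stream (versions + duplicates)
    sidecar: dict  # ground truth, JSON-serializable


def _inject_typo(name: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(name)))
    alphabet = string.ascii_lowercase.replace(name[pos].lower(), "") or "x"
    ch = alphabet[int(rng.integers(0, len(alphabet)))]
    return name[:pos] + ch + name[pos + 1 :]


def generate(cfg: SimConfig) -> SimOutput:
    """Generate the raw (pre-dedup) report stream plus the truth sidecar.

    Deterministic for a fixed config: two runs with the same seed are
    identical record for record.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    n_drugs = len(cfg.drug_catalog)
    n_events = len(cfg.event_catalog)
    drug_p = np.array([d.marginal_prob for d in cfg.drug_catalog])

    # drug draws: a first (suspect) drug by marginal probability, and with
    # probability second_drug_prob a second independent draw from the same
    # marginals (a collision with the first drug yields a one-drug report,
    # so rare drugs stay rare as co-medication)
    d1 = rng.choice(n_drugs, size=n, p=drug_p)
    d2 = rng.choice(n_drugs, size=n, p=drug_p)
    has2 = (rng.random(n) < cfg.second_drug_prob) & (d1 != d2)

    # event draws: per-PT Bernoulli with rate base * max-lambda over drugs
    lam = np.ones((n_drugs, n_events))
    ing_index = {d.ingredient: i for i, d in enumerate(cfg.drug_catalog)}
    pt_index = {e.pt: j for j, e in enumerate(cfg.event_catalog)}
    for (ing, pt), value in cfg.planted_lambda.items():
        if ing not in ing_index or pt not in pt_index:
            raise SimConfigError(f"planted lambda names unknown pair ({ing}, {pt})")
        lam[ing_index[ing], pt_index[pt]] = value
    base = np.array([e.base_rate for e in cfg.event_catalog])
    lam2 = np.where(has2[:, None], lam[d2], 1.0)
    lam_max = np.maximum(lam[d1], lam2)
    # deflate non-elevated reports so the marginal PT rate stays at base
    # and the planted multiplier equals the reporting ratio exactly
    multiplier = lam_max.copy()
    for j in range(n_events):
        col = lam_max[:, j]
        elevated = col != 1.0
        n_plain = int((~elevated).sum())
        if elevated.any():
            if n_plain == 0:
                raise SimConfigError(
                    f"every report elevates PT {cfg.event_catalog[j].pt!r}; "
                    "cannot hold its marginal rate at base_rate"
                )
            deflate = (n - float(col[elevated].sum())) / n_plain
            if deflate < 0:
                raise SimConfigError(
                    f"planted lambdas too large for PT {cfg.event_catalog[j].pt!r}"
                )
            multiplier[~elevated, j] = deflate
    rates = base[None, :] * multiplier
    events = rng.random((n, n_events)) < rates

    # demographics
    ages = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), 18.0, 100.0)
    age_missing = rng.random(n) < cfg.missing_age_prob
    sex_draw = rng.choice(3, size=n, p=cfg.sex_probs)
    reporter_draw = rng.choice(3, size=n, p=cfg.reporter_probs)
    country_draw = rng.choice(len(cfg.countries), size=n, p=cfg.country_probs)

    # dates
    span = (cfg.window_end - cfg.window_start).days
    receipt_ord = rng.integers(0, span + 1, size=n)
    start_back = rng.integers(30, 400, size=n)  # exposure began before receipt
    missing_start = rng.random(n) < cfg.missing_start_prob
    missing_event = rng.random(n) < cfg.missing_event_prob
    partial_start = rng.random(n) < cfg.partial_date_prob

    # outcomes: one categorical draw per report (remainder = none), with a
    # small chance of one extra category to exercise multi-valued sets
    outcome_order = list(cfg.outcome_probs)
    outcome_cum = np.cumsum([cfg.outcome_probs[o] for o in outcome_order])
    outcome_u = rng.random(n)
    extra_outcome = rng.random(n) < cfg.extra_outcome_prob
    extra_pick = rng.integers(0, len(outcome_order), size=n)

    # duplicates / versions
    make_dup = rng.random(n) < cfg.dup_prob
    make_version = rng.random(n) < cfg.version_prob
    version_back = rng.integers(30, 200, size=n)

    sexes = (Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)
    reporters = (
        ReporterType.HEALTH_PROFESSIONAL,
        ReporterType.NON_HEALTH_PROFESSIONAL,
        ReporterType.UNKNOWN,
    )

    reports: list[SafetyReport] = []
    duplicates: list[SafetyReport] = []
    dup_pairs: list[tuple[str, str]] = []
    versioned_ids: list[str] = []
    canonical_receipts: dict[str, str] = {}

    for i in range(n):
        rid = f"R{i:07d}"
        receipt = cfg.window_start + datetime.timedelta(days=int(receipt_ord[i]))
        start = receipt - datetime.timedelta(days=int(start_back[i]))
        report_drugs = [int(d1[i])] + ([int(d2[i])] if has2[i] else [])
        pts = [cfg.event_catalog[j].pt for j in range(n_events) if events[i, j]]

        # time to onset: realized from the log-normal of the first planted
        # (drug, pt) pair present, else from the default distribution
        event_date: Optional[PartialDate] = None
        if pts:
            params = cfg.default_tto
            for k in report_drugs:
                ing = cfg.drug_catalog[k].ingredient
                for pt in pts:
                    if (ing, pt) in cfg.tto_lognormal:
                        params = cfg.tto_lognormal[(ing, pt)]
                        break
                else:
                    continue
                break
            median_days, sigma = params
            days = int(round(rng.lognormal(math.log(median_days), sigma)))
            event_date = PartialDate(start + datetime.timedelta(days=days))

        entries: list[DrugEntry] = []
        for pos, k in enumerate(report_drugs):
            spec = cfg.drug_catalog[k]
            syn = spec.synonyms[int(rng.integers(0, len(spec.synonyms)))]
            if rng.random() < cfg.typo_prob:
                syn = _inject_typo(syn, rng)
            if pos == 0:
                role = DrugRole.PRIMARY_SUSPECT
            else:
                role = (
                    DrugRole.SECONDARY_SUSPECT
                    if rng.random() < 0.5
                    else DrugRole.CONCOMITANT
                )
            start_pd: Optional[PartialDate] = None
            if not missing_start[i]:
                if partial_start[i]:
                    start_pd = PartialDate(start.replace(day=1), Precision.MONTH)
                else:
                    start_pd = PartialDate(start)
            entries.append(DrugEntry(verbatim_name=syn, role=role, start_date=start_pd))

        outcomes: set[Outcome] = set()
        idx = int(np.searchsorted(outcome_cum, outcome_u[i], side="right"))
        if idx < len(outcome_order):
            outcomes.add(outcome_order[idx])
            if extra_outcome[i]:
                outcomes.add(outcome_order[int(extra_pick[i])])

        report = SafetyReport(
            report_id=rid,
            case_id=rid,
            receipt_date=PartialDate(receipt),
            patient_age_years=None if age_missing[i] else float(ages[i]),
            patient_sex=sexes[sex_draw[i]],
            reporter_type=reporters[reporter_draw[i]],
            country=cfg.countries[country_draw[i]],
            event_date=None if missing_event[i] else event_date,
            drugs=entries,
            reactions=pts,
            outcomes=outcomes,
            report_year=receipt.year,
        )

        if make_version[i]:
            draft_receipt = receipt - datetime.timedelta(days=int(version_back[i]))
            draft = dataclasses.replace(
                report,
                receipt_date=PartialDate(draft_receipt),
                reactions=pts[:-1] if len(pts) > 1 else list(pts),
                drugs=[dataclasses.replace(e) for e in entries],
                outcomes=set(outcomes),
                report_year=draft_receipt.year,
            )
            reports.append(draft)
            versioned_ids.append(rid)
            canonical_receipts[rid] = receipt.isoformat()
        reports.append(report)

        if make_dup[i]:
            dup_id = f"D{i:07d}"
            clone = dataclasses.replace(
                report,
                report_id=dup_id,
                case_id=dup_id,
                drugs=[dataclasses.replace(e) for e in entries],
                reactions=list(pts),
                outcomes=set(outcomes),
            )
            assert duplicate_key(clone) == duplicate_key(report)
            duplicates.append(clone)
            dup_pairs.append((rid, dup_id))

    reports.extend(duplicates)

    sidecar = {
        "schema_version": 1,
        "seed": cfg.seed,
        "n_base_reports": n,
        "n_emitted": len(reports),
        "duplicate_pairs": [list(p) for p in dup_pairs],
        "versioned_ids": versioned_ids,
        "canonical_receipts": canonical_receipts,
        "lambda": {f"{ing}|{pt}": v for (ing, pt), v in cfg.planted_lambda.items()},
        "tto": {
            f"{ing}|{pt}": list(v) for (ing, pt), v in cfg.tto_lognormal.items()
        },
        "drug_catalog": [
            {
                "ingredient": d.ingredient,
                "class": d.drug_class.value,
                "synonyms": list(d.synonyms),
                "marginal_prob": d.marginal_prob,
            }
            for d in cfg.drug_catalog
        ],
        "event_catalog": [
            {"pt": e.pt, "smq_codes": list(e.smq_codes), "base_rate": e.base_rate}
            for e in cfg.event_catalog
        ],
    }
    return SimOutput(reports=reports, sidecar=sidecar)


def archive_from_sidecar(sidecar: dict) -> DrugArchive:
    """Rebuild the drug archive implied by the generator's catalog."""
    rows = []
    for d in sidecar["drug_catalog"]:
        for syn in {d["ingredient"], *d["synonyms"]}:
            rows.append(ArchiveRow(syn, d["ingredient"], DrugClass(d["class"]), "both"))
    return DrugArchive(rows)


def smq_definitions_from_sidecar(sidecar: dict):
    """SMQ definitions whose members are the generator's event catalog.

    Bundled headers supply names/parents; each catalog PT joins every SMQ
    code it was generated under.
    """
    import dataclasses as _dc

    from .vocab import SMQDefinition, bundled_smq_headers

    defs = {
        code: _dc.replace(d, member_pts=set())
        for code, d in bundled_smq_headers().items()
    }
    for ev in sidecar["event_catalog"]:
        for code in ev["smq_codes"]:
            defs.setdefault(
                code, SMQDefinition(code, f"SMQ {code}", "narrow")
            ).member_pts.add(ev["pt"])
    return defs


@dataclasses.dataclass
class RecoveryReport:
    """Pass/fail comparison of pipeline output against planted truth."""

    dedup_ok: bool
    dedup_details: dict
    ratio_results: dict[str, dict]  # "ing|pt" -> {lambda, estimate, ok}
    tto_results: dict[str, dict]  # "ing|pt" -> {median_true, median_est, ok}

    @property
    def passed(self) -> bool:
        return (
            self.dedup_ok
            and all(r["ok"] for r in self.ratio_results.values())
            and all(r["ok"] for r in self.tto_results.values())
        )


def truth_check(
    clean_reports: Sequence[SafetyReport],
    sidecar: dict,
    ratio_band: tuple[float, float] = (0.8, 1.25),
    tto_band: tuple[float, float] = (0.93, 1.08),
    min_tto_records: int = 2000,
) -> RecoveryReport:
    """Compare deduplicated, mapped pipeline output to the sidecar truth.

    Checks that each planted duplicate pair and each versioned id has
    exactly one survivor, that each planted lambda is recovered by the
    shrunk reporting ratio within ``lambda * ratio_band``, and that each
    configured log-normal onset median is recovered within
    ``median * tto_band`` (pairs with fewer than ``min_tto_records``
    usable records are reported but not failed — the median of a handful
    of draws is uninformative).
    """
    if sidecar.get("schema_version") != 1:
        raise ValueError("unrecognized sidecar schema")
    ids: dict[str, int] = {}
    receipt_of: dict[str, str] = {}
    for r in clean_reports:
        ids[r.report_id] = ids.get(r.report_id, 0) + 1
        if r.receipt_date is not None:
            receipt_of[r.report_id] = r.receipt_date.isoformat()

    dedup_problems: list[str] = []
    for orig, dup in sidecar["duplicate_pairs"]:
        survivors = ids.get(orig, 0) + ids.get(dup, 0)
        if survivors != 1:
            dedup_problems.append(f"pair ({orig},{dup}): {survivors} survivors")
    for rid in sidecar["versioned_ids"]:
        # at most one row per id may remain, and if the id survived it must
        # be the canonical (latest) version; a versioned id may legitimately
        # vanish altogether when the six-field rule collapses it into
        # another identical report
        if ids.get(rid, 0) > 1:
            dedup_problems.append(f"versioned {rid}: {ids[rid]} survivors")
        elif ids.get(rid, 0) == 1:
            expected = sidecar.get("canonical_receipts", {}).get(rid)
            if expected is not None and receipt_of.get(rid) != expected:
                dedup_problems.append(f"versioned {rid}: draft version survived")
    dedup_ok = not dedup_problems

    # map drugs, then estimate each planted pair's shrunk ratio
    archive = archive_from_sidecar(sidecar)
    mapped = list(clean_reports)
    map_reports(mapped, archive, fuzzy=True)
    analyses = [
        Analysis(key, f"ingredient:{key.split('|')[0]}", ("pt", key.split("|")[1]))
        for key in sidecar["lambda"]
    ]
    ratio_results: dict[str, dict] = {}
    if analyses:
        estimates = run_panel(mapped, analyses, archive, cfg=DEFAULT_CONFIG)
        for est in estimates:
            lam = sidecar["lambda"][est.name]
            lo, hi = lam * ratio_band[0], lam * ratio_band[1]
            ratio_results[est.name] = {
                "lambda": lam,
                "estimate": est.ror_shrunk,
                "ic_low": est.ic_low,
                "ok": lo <= est.ror_shrunk <= hi,
            }

    tto_results: dict[str, dict] = {}
    for key, (median_true, sigma) in sidecar["tto"].items():
        ing, pt = key.split("|")
        records, _ = collect_tto(mapped, {ing}, pt_predicate([pt]), event_group=pt)
        if not records:
            tto_results[key] = {
                "median_true": median_true,
                "median_est": None,
                "n": 0,
                "ok": True,
            }
            continue
        summary = summarize_tto(records)
        lo, hi = median_true * tto_band[0], median_true * tto_band[1]
        tto_results[key] = {
            "median_true": median_true,
            "median_est": summary.median,
            "n": summary.n,
            "ok": (summary.n < min_tto_records) or (lo <= summary.median <= hi),
        }

    return RecoveryReport(
        dedup_ok=dedup_ok,
        dedup_details={"problems": dedup_problems},
        ratio_results=ratio_results,
        tto_results=tto_results,
    )
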