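"""Drug-name normalization and PT-to-SMQ mapping.

Drug products arrive as free text — generic names, brand names, research
codes, combination products, misspellings.  A drug archive maps each
known synonym to an ingredient and a pharmacological class.  Adverse
events arrive as MedDRA preferred terms (PTs) and are grouped into
standardized queries (SMQs); because MedDRA content is licensed, SMQ
membership is supplied by the user as a CSV, and the package bundles
only SMQ headers (codes, names, scopes, parent links) plus a curated
drug archive for VEGF(R)-pathway angiogenesis inhibitors.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import edlib

from .model import DrugClass, MAB_SUPERCLASS, TKI_SUPERCLASS, SafetyReport


class VocabError(Exception):
    """Archive or SMQ file problem (collisions, malformed rows)."""


_PUNCT = re.compile(r"[^\w\s]+", re.UNICODE)
_SPACES = re.compile(r"\s+")


def canonicalize(text: str) -> str:
    """Case-fold, trim, strip punctuation, collapse internal whitespace."""
    return _SPACES.sub(" ", _PUNCT.sub(" ", text.casefold())).strip()


#: Separators splitting combination products into components.
_COMBO = re.compile(r"[/+]")


def split_components(verbatim: str) -> list[str]:
    """Split a combination product ("drug A / drug B") into components."""
    parts = [p.strip() for p in _COMBO.split(verbatim)]
    return [p for p in parts if p] or [verbatim.strip()]


@dataclasses.dataclass(frozen=True)
class ArchiveRow:
    synonym: str
    ingredient: str
    drug_class: DrugClass
    approval_region: str  # FDA | NMPA | both


class DrugArchive:
    """Synonym -> (ingredient, class) lookup with canonicalized keys.

    Loading fails loudly if two rows canonicalize to the same synonym but
    map to different ingredients, and every ingredient must appear as its
    own synonym.
    """

    def __init__(self, rows: Iterable[ArchiveRow]):
        self._by_synonym: dict[str, ArchiveRow] = {}
        ingredients: set[str] = set()
        self_synonyms: set[str] = set()
        for row in rows:
            key = canonicalize(row.synonym)
            if not key:
                raise VocabError(f"empty synonym after canonicalization: {row!r}")
            existing = self._by_synonym.get(key)
            if existing is not None and existing.ingredient != row.ingredient:
                raise VocabError(
                    f"synonym collision: {key!r} maps to both "
                    f"{existing.ingredient!r} and {row.ingredient!r}"
                )
            self._by_synonym[key] = row
            ingredients.add(row.ingredient)
            if key == canonicalize(row.ingredient):
                self_synonyms.add(row.ingredient)
        orphans = ingredients - self_synonyms
        if orphans:
            raise VocabError(
                f"ingredient(s) without a self-synonym: {sorted(orphans)}"
            )
        self._class_of = {
            canonicalize(r.ingredient): r.drug_class
            for r in self._by_synonym.values()
        }
        self._ingredient_name = {
            canonicalize(r.ingredient): r.ingredient
            for r in self._by_synonym.values()
        }

    def __len__(self) -> int:
        return len(self._by_synonym)

    def lookup(self, canon: str) -> Optional[ArchiveRow]:
        return self._by_synonym.get(canon)

    @property
    def synonyms(self) -> list[str]:
        return list(self._by_synonym)

    def ingredients(self) -> set[str]:
        return set(self._ingredient_name.values())

    def ingredients_in_classes(self, classes: frozenset[DrugClass]) -> set[str]:
        return {
            name
            for canon, name in self._ingredient_name.items()
            if self._class_of[canon] in classes
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugArchive":
        rows = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"synonym", "ingredient", "class", "region"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise VocabError(f"{path}: missing column(s) {sorted(missing)}")
            for row in reader:
                rows.append(
                    ArchiveRow(
                        synonym=row["synonym"],
                        ingredient=row["ingredient"],
                        drug_class=DrugClass(row["class"]),
                        approval_region=row["region"],
                    )
                )
        return cls(rows)


def bundled_archive() -> DrugArchive:
    """The curated archive of VEGF(R)-targeted angiogenesis inhibitors
    (21 agents with generic names, common brand names and research codes;
    curated by the package authors, not an official product dictionary)."""
    with resources.files("vigisig.data").joinpath("drug_archive.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        reader = csv.DictReader(fh)
        rows = [
            ArchiveRow(r["synonym"], r["ingredient"], DrugClass(r["class"]), r["region"])
            for r in reader
        ]
    return DrugArchive(rows)


def normalize_drug(
    verbatim: str, archive: DrugArchive, fuzzy: bool = False
) -> Optional[str]:
    """Map one verbatim product token to an ingredient, or None if unmapped.

    Exact canonicalized match first; with ``fuzzy`` enabled, a synonym at
    edit distance exactly 1 is accepted when it is unique (two candidate
    synonyms mapping to different ingredients -> unmapped).
    """
    canon = canonicalize(verbatim)
    if not canon:
        return None
    row = archive.lookup(canon)
    if row is not None:
        return row.ingredient
    if not fuzzy:
        return None
    candidates: set[str] = set()
    for syn in archive.synonyms:
        if abs(len(syn) - len(canon)) > 1:
            continue
        if edlib.align(canon, syn, k=1)["editDistance"] == 1:
            candidates.add(archive.lookup(syn).ingredient)  # type: ignore[union-attr]
    if len(candidates) == 1:
        return candidates.pop()
    return None


def classify_drug(ingredient: str, archive: DrugArchive) -> DrugClass:
    """Return the archive's class for a mapped ingredient."""
    cls = archive._class_of.get(canonicalize(ingredient))
    if cls is None:
        raise VocabError(f"unknown ingredient: {ingredient!r}")
    return cls


# ---------------------------------------------------------------------------
# SMQ definitions
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SMQDefinition:
    smq_code: int
    smq_name: str
    scope: str  # narrow | broad
    parent_code: Optional[int] = None
    member_pts: set[str] = dataclasses.field(default_factory=set)

    def canonical_members(self) -> set[str]:
        return {canonicalize(pt) for pt in self.member_pts}


def load_smq_csv(path: str | Path) -> dict[int, SMQDefinition]:
    """Load SMQ definitions from a CSV with columns
    smq_code,smq_name,scope,parent_code,pt_name (pt_name empty for a
    header-only row)."""
    defs: dict[int, SMQDefinition] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"smq_code", "smq_name", "scope", "parent_code", "pt_name"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise VocabError(f"{path}: missing column(s) {sorted(missing)}")
        for row in reader:
            code = int(row["smq_code"])
            d = defs.setdefault(
                code,
                SMQDefinition(
                    smq_code=code,
                    smq_name=row["smq_name"],
                    scope=row["scope"] or "narrow",
                    parent_code=int(row["parent_code"]) if row["parent_code"] else None,
                ),
            )
            if row["pt_name"]:
                d.member_pts.add(row["pt_name"])
    return defs


def bundled_smq_headers() -> dict[int, SMQDefinition]:
    """The nine narrow cardiovascular SMQ headers plus the embolic and
    thrombotic sub-SMQs (arterial, venous, vessel-unspecified/mixed),
    without member PTs — membership is licensed content supplied by the
    user."""
    with resources.files("vigisig.data").joinpath("smq_headers.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        reader = csv.DictReader(fh)
        defs: dict[int, SMQDefinition] = {}
        for row in reader:
            code = int(row["smq_code"])
            defs[code] = SMQDefinition(
                smq_code=code,
                smq_name=row["smq_name"],
                scope=row["scope"],
                parent_code=int(row["parent_code"]) if row["parent_code"] else None,
            )
    return defs


def map_pt_to_smqs(pt: str, defs: dict[int, SMQDefinition]) -> set[int]:
    """All narrow SMQs containing the PT, closed upward over parent links."""
    canon = canonicalize(pt)
    hits = {
        code
        for code, d in defs.items()
        if d.scope == "narrow" and canon in d.canonical_members()
    }
    closed = set(hits)
    frontier = list(hits)
    while frontier:
        code = frontier.pop()
        parent = defs[code].parent_code
        if parent is not None and parent in defs and parent not in closed:
            closed.add(parent)
            frontier.append(parent)
    return closed


# ---------------------------------------------------------------------------
# applying the vocabularies to reports
# ---------------------------------------------------------------------------


def map_reports(
    reports: list[SafetyReport],
    archive: DrugArchive,
    fuzzy: bool = False,
) -> tuple[list[SafetyReport], dict[str, int]]:
    """Fill ingredient/class on every drug entry, in place.

    Combination products are split on '/' and '+'; if several components
    map, the entry is expanded into one entry per mapped component
    (sharing role and start date).  Returns the reports and mapping
    counters.
    """
    counters = {"mapped": 0, "unmapped": 0, "expanded_combinations": 0}
    for r in reports:
        new_entries = []
        for d in r.drugs:
            components = split_components(d.verbatim_name)
            mapped = [
                ing
                for c in components
                if (ing := normalize_drug(c, archive, fuzzy=fuzzy)) is not None
            ]
            mapped = list(dict.fromkeys(mapped))  # dedupe, keep order
            if not mapped:
                counters["unmapped"] += 1
                new_entries.append(d)
                continue
            counters["mapped"] += 1
            if len(mapped) > 1:
                counters["expanded_combinations"] += 1
            d.ingredient = mapped[0]
            d.drug_class = classify_drug(mapped[0], archive)
            new_entries.append(d)
            for extra in mapped[1:]:
                new_entries.append(
                    dataclasses.replace(
                        d,
                        ingredient=extra,
                        drug_class=classify_drug(extra, archive),
                    )
                )
        r.drugs = new_entries
    return reports, counters


def resolve_drug_spec(spec: str | set[str], archive: DrugArchive) -> set[str]:
    """Resolve a drug spec to an ingredient set.

    Accepted forms: a set of ingredients, ``"ingredient:NAME"``,
    ``"class:TKI"`` (any :class:`DrugClass` value), or the superclass
    aliases ``"class:mAb"`` / ``"class:TKI"``.
    """
    if isinstance(spec, set):
        unknown = spec - archive.ingredients()
        if unknown:
            raise VocabError(f"unknown ingredient(s) in drug spec: {sorted(unknown)}")
        return set(spec)
    kind, _, value = spec.partition(":")
    if kind == "ingredient":
        if value not in archive.ingredients():
            raise VocabError(f"unknown ingredient in drug spec: {value!r}")
        return {value}
    if kind == "class":
        if value == "mAb":
            return archive.ingredients_in_classes(MAB_SUPERCLASS)
        if value == "TKI":
            return archive.ingredients_in_classes(TKI_SUPERCLASS)
        try:
            cls = DrugClass(value)
        except ValueError:
            raise VocabError(f"unknown drug class in spec: {value!r}") from None
        return archive.ingredients_in_classes(frozenset({cls}))
    raise VocabError(f"unparseable drug spec: {spec!r}")
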