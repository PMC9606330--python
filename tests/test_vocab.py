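"""Drug-name normalization, class lookup, and PT -> SMQ mapping."""

import pytest

from vigisig.model import DrugClass
from vigisig.vocab import (
    ArchiveRow,
    DrugArchive,
    SMQDefinition,
    VocabError,
    bundled_archive,
    bundled_smq_headers,
    canonicalize,
    classify_drug,
    load_smq_csv,
    map_pt_to_smqs,
    map_reports,
    normalize_drug,
    resolve_drug_spec,
    split_components,
)


@pytest.fixture(scope="module")
def archive():
    return bundled_archive()


@pytest.mark.parametrize(
    "verbatim, ingredient",
    [
        ("AVASTIN", "bevacizumab"),  # brand name
        ("bevacizumab.", "bevacizumab"),  # trailing punctuation
        ("  Sutent  ", "sunitinib"),
        ("SU11248", "sunitinib"),  # research code
        ("Nexavar", "sorafenib"),
        ("ZALTRAP", "aflibercept"),
    ],
)
def test_exact_normalization_through_the_archive(archive, verbatim, ingredient):
    assert normalize_drug(verbatim, archive) == ingredient


def test_normalization_is_case_insensitive(archive):
    for name in ("avastin", "Lenvima", "cometriq"):
        assert normalize_drug(name, archive) == normalize_drug(name.upper(), archive)


def test_fuzzy_match_requires_flag_and_uniqueness(archive):
    assert normalize_drug("bevacizumeb", archive, fuzzy=False) is None
    assert normalize_drug("bevacizumeb", archive, fuzzy=True) == "bevacizumab"
    assert normalize_drug("totally unknown drug", archive, fuzzy=True) is None


def test_empty_string_is_unmapped(archive):
    assert normalize_drug("", archive) is None
    assert normalize_drug("  . ", archive) is None


@pytest.mark.parametrize(
    "ingredient, cls",
    [
        ("bevacizumab", DrugClass.ANTI_VEGF_MAB),
        ("aflibercept", DrugClass.VEGF_TRAP),
        ("ramucirumab", DrugClass.ANTI_VEGFR_MAB),
        ("sunitinib", DrugClass.TKI),
        ("recombinant human endostatin", DrugClass.OTHER_ANTIANGIOGENIC),
    ],
)
def test_drug_class_lookup(archive, ingredient, cls):
    assert classify_drug(ingredient, archive) is cls


def test_unknown_ingredient_raises(archive):
    with pytest.raises(VocabError, match="unknown ingredient"):
        classify_drug("aspirin", archive)


def test_superclass_resolution_covers_mabs_and_tkis(archive):
    mabs = resolve_drug_spec("class:mAb", archive)
    tkis = resolve_drug_spec("class:TKI", archive)
    assert {"bevacizumab", "ramucirumab", "aflibercept"} <= mabs
    assert {"sunitinib", "cediranib", "vandetanib"} <= tkis
    assert not mabs & tkis


def test_combination_products_split_into_components():
    assert split_components("drug A / drug B") == ["drug A", "drug B"]
    assert split_components("bevacizumab+irinotecan") == ["bevacizumab", "irinotecan"]
    assert split_components("plain") == ["plain"]


def test_synonym_collision_fails_loudly():
    rows = [
        ArchiveRow("drugx", "drugx", DrugClass.TKI, "FDA"),
        ArchiveRow("drugy", "drugy", DrugClass.TKI, "FDA"),
        ArchiveRow("Samebrand", "drugx", DrugClass.TKI, "FDA"),
        ArchiveRow("samebrand", "drugy", DrugClass.TKI, "FDA"),
    ]
    with pytest.raises(VocabError, match="collision"):
        DrugArchive(rows)


def test_every_ingredient_needs_a_self_synonym():
    rows = [ArchiveRow("brandonly", "someingredient", DrugClass.TKI, "FDA")]
    with pytest.raises(VocabError, match="self-synonym"):
        DrugArchive(rows)


# ---------------------------------------------------------------------------
# SMQs
# ---------------------------------------------------------------------------

SMQ_CSV = """smq_code,smq_name,scope,parent_code,pt_name
20000147,Hypertension,narrow,,Hypertension
20000147,Hypertension,narrow,,Blood pressure increased
20000081,Embolic and thrombotic events,narrow,,
20000084,"Embolic and thrombotic events, venous",narrow,20000081,Pulmonary embolism
20000084,"Embolic and thrombotic events, venous",narrow,20000081,Deep vein thrombosis
90000001,Some broad group,broad,,Hypertension
"""


@pytest.fixture()
def smq_defs(tmp_path):
    p = tmp_path / "smq.csv"
    p.write_text(SMQ_CSV, encoding="utf-8")
    return load_smq_csv(p)


def test_pt_maps_to_its_narrow_smq_only(smq_defs):
    # broad-scope membership is ignored
    assert map_pt_to_smqs("Hypertension", smq_defs) == {20000147}
    assert map_pt_to_smqs("HYPERTENSION  ", smq_defs) == {20000147}


def test_unknown_pt_maps_nowhere(smq_defs):
    assert map_pt_to_smqs("Nail disorder", smq_defs) == set()


def test_sub_smq_membership_closes_over_the_parent(smq_defs):
    assert map_pt_to_smqs("Pulmonary embolism", smq_defs) == {20000084, 20000081}


def test_bundled_headers_carry_the_nine_narrow_categories():
    defs = bundled_smq_headers()
    assert defs[20000147].smq_name == "Hypertension"
    assert defs[20000081].smq_name == "Embolic and thrombotic events"
    assert {20000049, 20000004, 20000150, 20000043, 20000239, 20000130, 20000001} <= set(defs)
    subs = {c for c, d in defs.items() if d.parent_code == 20000081}
    assert subs == {20000082, 20000083, 20000084}
    # headers only: membership is licensed content the user supplies
    assert all(not d.member_pts for d in defs.values())


def test_map_reports_fills_ingredients_and_expands_combos(make_report, archive):
    r = make_report()
    from vigisig.model import DrugEntry, DrugRole

    r.drugs = [
        DrugEntry("AVASTIN / irinotecan", role=DrugRole.PRIMARY_SUSPECT),
        DrugEntry("sutent"),
        DrugEntry("mystery tonic"),
    ]
    _, counters = map_reports([r], archive)
    assert [d.ingredient for d in r.drugs] == ["bevacizumab", "sunitinib", None]
    assert r.drugs[0].drug_class is DrugClass.ANTI_VEGF_MAB
    assert counters["unmapped"] == 1
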