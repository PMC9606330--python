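"""Contingency construction and the shrinkage ROR/IC machinery."""

import math
import random

import pytest

from vigisig.model import DrugRole, SUSPECT_ROLES
from vigisig.signal_stats import (
    Analysis,
    ContingencyTable,
    DEFAULT_CONFIG,
    ShrinkageConfig,
    SignalError,
    SignalEstimate,
    build_contingency,
    detect_signal,
    estimate_cell,
    ic_stats,
    pt_predicate,
    ror_ci,
    round_half_away,
    run_panel,
    shrunk_ratio,
)
from vigisig.synthetic import SimConfig, generate, archive_from_sidecar
from vigisig.dedup import deduplicate
from vigisig.vocab import map_reports


def brute_force_table(reports, target_drugs, target_events, roles=SUSPECT_ROLES):
    """Independent per-report classifier used as the oracle."""
    cells = {"a": 0, "b": 0, "c": 0, "d": 0}
    for r in reports:
        exposed = False
        for entry in r.drugs:
            if entry.ingredient in target_drugs and entry.role in roles:
                exposed = True
        event = target_events(r)
        if exposed and event:
            cells["a"] += 1
        elif exposed and not event:
            cells["b"] += 1
        elif event:
            cells["c"] += 1
        else:
            cells["d"] += 1
    return ContingencyTable(cells["a"], cells["b"], cells["c"], cells["d"])


def test_contingency_enumeration_on_the_six_report_toy_set(make_report):
    # reports: (X,Y) (X,Z) (W,Y) (W,Z) (XW,YZ) (W,Z); target drug X, event Y
    rows = [
        (["X"], ["Y"]),
        (["X"], ["Z"]),
        (["W"], ["Y"]),
        (["W"], ["Z"]),
        (["X", "W"], ["Y", "Z"]),
        (["W"], ["Z"]),
    ]
    reports = [make_report(drugs=d, reactions=e) for d, e in rows]
    t = build_contingency(reports, {"X"}, pt_predicate(["Y"]))
    assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
    assert t.n_drug == 3 and t.n_event == 3 and t.n_total == 6
    assert t.n_expected == pytest.approx(1.5)


def test_absent_target_drug_gives_empty_exposure(make_report):
    reports = [make_report(drugs=["W"], reactions=["Y"]) for _ in range(4)]
    t = build_contingency(reports, {"X"}, pt_predicate(["Y"]))
    assert t.a == 0 and t.b == 0 and t.c == 4


def test_event_predicate_matching_everything_forces_b_zero(make_report):
    reports = [
        make_report(drugs=["X"], reactions=["Y"]),
        make_report(drugs=["W"], reactions=["Z"]),
        make_report(drugs=["W"], reactions=["Y"]),
    ]
    t = build_contingency(reports, {"X"}, lambda r: True)
    assert t.b == 0 and t.c == 2 and t.d == 0


def test_empty_report_list_is_an_error():
    with pytest.raises(SignalError):
        build_contingency([], {"X"}, lambda r: True)


def test_role_filter_excludes_concomitant_exposure(make_report):
    reports = [
        make_report(drugs=[("X", DrugRole.CONCOMITANT)], reactions=["Y"]),
        make_report(drugs=[("X", DrugRole.SECONDARY_SUSPECT)], reactions=["Y"]),
        make_report(drugs=["W"], reactions=["Z"]),
    ]
    t = build_contingency(reports, {"X"}, pt_predicate(["Y"]))
    assert t.a == 1 and t.c == 1  # concomitant-only report is unexposed


def test_contingency_matches_brute_force_on_random_small_instances(make_report):
    rng = random.Random(42)
    drugs = ["X", "W", "V"]
    pts = ["Y", "Z", "Q"]
    roles = list(DrugRole)
    for _ in range(200):
        reports = []
        for i in range(rng.randint(1, 20)):
            ds = [
                (rng.choice(drugs), rng.choice(roles))
                for _ in range(rng.randint(0, 3))
            ]
            es = [rng.choice(pts) for _ in range(rng.randint(0, 3))]
            reports.append(make_report(drugs=ds or ["filler"], reactions=es))
        target = {rng.choice(drugs)}
        pred = pt_predicate([rng.choice(pts)])
        assert build_contingency(reports, target, pred) == brute_force_table(
            reports, target, pred
        )


# ---------------------------------------------------------------------------
# shrunk ratio / IC / ROR CI
# ---------------------------------------------------------------------------

T3_7_30_60 = ContingencyTable(3, 7, 30, 60)  # n_expected = 3.3


def test_shrunk_ratio_hand_value():
    assert shrunk_ratio(T3_7_30_60) == pytest.approx(3.5 / 3.8)


def test_shrunk_ratio_is_one_when_observed_equals_expected():
    # a = 10, n_drug = 20, n_event = 50, n_total = 100 -> expected 10
    t = ContingencyTable(10, 10, 40, 40)
    assert shrunk_ratio(t) == pytest.approx(1.0)


def test_shrunk_ratio_defined_at_zero_observed():
    t = ContingencyTable(0, 0, 0, 5)
    assert shrunk_ratio(t) == pytest.approx(1.0)  # 0.5 / 0.5


def test_ic_stats_high_precision_closed_forms():
    ratio = shrunk_ratio(T3_7_30_60)
    ic, low, high = ic_stats(3, ratio)
    assert ic == pytest.approx(-0.1186444964986189, abs=1e-9)
    assert low == pytest.approx(-2.188010112449105, abs=1e-9)
    assert high == pytest.approx(1.087849109848897, abs=1e-9)


def test_ror_ci_classical_hand_value():
    low, high = ror_ci(T3_7_30_60, point="classical")
    assert low == pytest.approx(0.2068183, abs=1e-6)
    assert high == pytest.approx(3.5523647, abs=1e-6)


def test_ror_ci_symmetric_table_identity():
    # a = d, b = c: classical point is (a/b)^2 and the CI is symmetric in logs
    t = ContingencyTable(6, 3, 3, 6)
    low, high = ror_ci(t, point="classical")
    assert low * high == pytest.approx(4.0**2)


def test_ror_ci_zero_cell_is_undefined_not_substituted():
    assert ror_ci(ContingencyTable(0, 7, 30, 60)) == (None, None)


def test_shrunk_point_estimate_is_the_default_ci_center():
    low, high = ror_ci(T3_7_30_60)
    assert math.sqrt(low * high) == pytest.approx(shrunk_ratio(T3_7_30_60))


# ---------------------------------------------------------------------------
# signal rule
# ---------------------------------------------------------------------------


def _est(n, ror_low, ic_low):
    return SignalEstimate(
        name="x",
        n_observed=n,
        ror_shrunk=1.0,
        ror_ci_low=ror_low,
        ror_ci_high=None,
        ic=0.0,
        ic_low=ic_low,
        ic_high=1.0,
        is_signal=False,
    )


@pytest.mark.parametrize(
    "n, ror_low, ic_low, expected",
    [
        (26, 0.89, -0.24, False),  # neither bound clears its threshold
        (2, 50.0, 5.0, False),  # below the three-report minimum
        (1000, 0.99, 0.01, True),  # IC clause alone suffices (OR rule)
        (1000, 1.01, -0.5, True),  # ROR clause alone suffices
        (3, None, 0.2, True),  # undefined ROR bound falls back to IC
        (3, None, -0.2, False),
    ],
)
def test_signal_rule(n, ror_low, ic_low, expected):
    assert detect_signal(_est(n, ror_low, ic_low)) is expected


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("a,b,c,d", [(3, 7, 30, 60), (0, 5, 5, 90), (40, 10, 20, 30), (1, 0, 0, 1)])
def test_ic_is_log2_of_the_shrunk_ratio(a, b, c, d):
    est = estimate_cell("x", ContingencyTable(a, b, c, d))
    assert est.ic == math.log2(est.ror_shrunk)
    assert est.ic_low < est.ic < est.ic_high


def test_shrinkage_pulls_toward_one():
    for t in [ContingencyTable(3, 7, 30, 60), ContingencyTable(40, 10, 20, 30), ContingencyTable(2, 50, 2, 50)]:
        raw = t.a / t.n_expected
        assert abs(math.log(shrunk_ratio(t))) <= abs(math.log(raw))


def test_interval_widths_shrink_monotonically_in_n():
    prev_low_w = prev_high_w = math.inf
    for n in [0, 1, 3, 10, 71, 104, 1000, 19385]:
        ic, low, high = ic_stats(n, 2.0)
        assert low < ic < high
        assert (ic - low) < prev_low_w and (high - ic) < prev_high_w
        prev_low_w, prev_high_w = ic - low, high - ic


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_study():
    cfg = SimConfig(
        n_reports=30_000,
        seed=13,
        dup_prob=0.0,
        version_prob=0.0,
        typo_prob=0.0,
        planted_lambda={("lenvatinib", "Blood pressure increased"): 8.0},
        tto_lognormal={},
    )
    sim = generate(cfg)
    clean, _ = deduplicate(sim.reports)
    archive = archive_from_sidecar(sim.sidecar)
    map_reports(clean, archive)
    return clean, archive, sim.sidecar


def test_planted_pair_is_the_unique_pt_level_signal(planted_study):
    clean, archive, sidecar = planted_study
    analyses = [
        Analysis(f"{d['ingredient']}|{e['pt']}", f"ingredient:{d['ingredient']}", ("pt", e["pt"]))
        for d in sidecar["drug_catalog"]
        if d["class"] != "non_target"
        for e in sidecar["event_catalog"]
    ]
    results = run_panel(clean, analyses, archive)
    signals = {r.name for r in results if r.is_signal}
    assert signals == {"lenvatinib|Blood pressure increased"}


def test_single_analysis_panel_equals_direct_computation(planted_study):
    clean, archive, _ = planted_study
    [row] = run_panel(
        clean,
        [Analysis("len-bpi", "ingredient:lenvatinib", ("pt", "Blood pressure increased"))],
        archive,
    )
    table = build_contingency(
        clean, {"lenvatinib"}, pt_predicate(["Blood pressure increased"])
    )
    direct = estimate_cell("len-bpi", table)
    assert (row.n_observed, row.ror_shrunk, row.ic_low) == (
        direct.n_observed,
        direct.ror_shrunk,
        direct.ic_low,
    )


def test_class_spec_aggregates_member_ingredients(planted_study):
    clean, archive, _ = planted_study
    [by_class] = run_panel(
        clean, [Analysis("tki", "class:TKI", ("pt", "Nausea"))], archive
    )
    tkis = {"sunitinib", "lenvatinib", "sorafenib"}
    direct = build_contingency(clean, tkis, pt_predicate(["Nausea"]))
    assert by_class.n_observed == direct.a


def test_unknown_drug_spec_is_a_named_error(planted_study):
    clean, archive, _ = planted_study
    from vigisig.vocab import VocabError

    with pytest.raises(VocabError, match="nosuchdrug"):
        run_panel(clean, [Analysis("bad", "ingredient:nosuchdrug", ("pt", "Nausea"))], archive)


# ---------------------------------------------------------------------------
# presentation rounding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, expected",
    [(2.6038, 2.60), (1.3785, 1.38), (0.125, 0.13), (-0.125, -0.13), (1.005, 1.01)],
)
def test_round_half_away_from_zero(x, expected):
    assert round_half_away(x, 2) == expected
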