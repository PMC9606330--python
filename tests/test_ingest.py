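"""Raw-table reading, partial dates, unit conversion, interchange round-trip."""

import datetime

import pytest

from vigisig.ingest import (
    IngestError,
    IngestLog,
    PartialDateError,
    convert_age,
    parse_partial_date,
    read_faers_ascii,
    read_interchange_csv,
    write_interchange_csv,
)
from vigisig.model import DrugRole, Outcome, Precision, Sex
from vigisig.synthetic import SimConfig, generate


@pytest.mark.parametrize(
    "token, date, precision",
    [
        ("202003", datetime.date(2020, 3, 1), Precision.MONTH),
        ("2020", datetime.date(2020, 1, 1), Precision.YEAR),
        ("20200315", datetime.date(2020, 3, 15), Precision.DAY),
        ("2020-03-15", datetime.date(2020, 3, 15), Precision.DAY),
        ("2020-03", datetime.date(2020, 3, 1), Precision.MONTH),
    ],
)
def test_parse_partial_date_returns_earliest_consistent_date(token, date, precision):
    pd_ = parse_partial_date(token)
    assert (pd_.date, pd_.precision) == (date, precision)


@pytest.mark.parametrize("token", ["20200230", "abc", "202", "2020-13", "20203"])
def test_parse_partial_date_rejects_malformed_tokens(token):
    with pytest.raises(PartialDateError):
        parse_partial_date(token)


@pytest.mark.parametrize(
    "value, unit, expected",
    [
        ("70", "MON", 70 / 12),  # ~5.83 years
        ("7", "DEC", 70.0),
        ("26", "WK", 26 / 52.1775),
        ("365", "DY", 365 / 365.25),
        ("65", "YR", 65.0),
        ("65", "", 65.0),  # missing unit defaults to years
    ],
)
def test_age_unit_conversion(value, unit, expected):
    log = IngestLog()
    assert convert_age(value, unit, log) == pytest.approx(expected)
    assert not log.counters


def test_age_out_of_range_and_unknown_unit_are_logged_missing():
    log = IngestLog()
    assert convert_age("999", "YR", log) is None
    assert convert_age("5", "LY", log) is None
    assert log.counters["age_out_of_range"] == 1
    assert log.counters["unknown_age_unit"] == 1


# ---------------------------------------------------------------------------
# '$'-delimited dialect
# ---------------------------------------------------------------------------


def _write_quarter(tmp_path, demo, drug="", reac="", outc="", ther=""):
    paths = {}
    for role, content in [
        ("demo", demo),
        ("drug", drug),
        ("reac", reac),
        ("outc", outc),
        ("ther", ther),
    ]:
        if content:
            p = tmp_path / f"{role.upper()}.txt"
            p.write_text(content, encoding="utf-8")
            paths[role] = p
    return paths


DEMO = (
    "primaryid$caseid$receiptdate$event_dt$age$age_cod$sex$occp_cod$reporter_country\n"
    "101$100$20200601$20200315$70$MON$F$MD$US\n"
)


def test_child_rows_join_onto_their_case(tmp_path):
    paths = _write_quarter(
        tmp_path,
        demo=DEMO,
        drug=(
            "primaryid$drug_seq$role_cod$drugname$start_dt\n"
            "101$1$PS$AVASTIN$20200301\n"
            "101$2$C$METFORMIN$\n"
        ),
        reac="primaryid$pt\n101$Hypertension\n101$Epistaxis\n",
        outc="primaryid$outc_cod\n101$HO\n101$DE\n",
        ther="primaryid$dsg_drug_seq$start_dt\n101$2$20200210\n",
    )
    result = read_faers_ascii(paths, quarter="2020Q2")
    assert len(result) == 1
    r = result.reports[0]
    assert r.report_id == "101" and r.case_id == "100"
    assert r.patient_age_years == pytest.approx(70 / 12)
    assert r.patient_sex is Sex.FEMALE
    assert [d.verbatim_name for d in r.drugs] == ["AVASTIN", "METFORMIN"]
    assert r.drugs[0].role is DrugRole.PRIMARY_SUSPECT
    # second drug's start date came from the therapy table by sequence id
    assert r.drugs[1].start_date.date == datetime.date(2020, 2, 10)
    assert r.reactions == ["Hypertension", "Epistaxis"]
    assert r.outcomes == {Outcome.HOSPITALIZATION, Outcome.DEATH}
    assert result.log.counters["n_cases_in"] == 1


def test_empty_reaction_file_counts_a_warning_per_case(tmp_path):
    demo = DEMO + "102$102$20200701$$$$M$CN$JP\n"
    paths = _write_quarter(tmp_path, demo=demo, reac="primaryid$pt\n")
    result = read_faers_ascii(paths)
    assert len(result) == 2
    assert all(r.reactions == [] for r in result.reports)
    assert result.log.counters["no_reactions"] == 2


def test_missing_mandatory_column_is_a_file_error(tmp_path):
    paths = _write_quarter(tmp_path, demo="caseid$receiptdate\n100$20200601\n")
    with pytest.raises(IngestError, match="primaryid"):
        read_faers_ascii(paths)


def test_duplicate_header_is_a_file_error(tmp_path):
    paths = _write_quarter(tmp_path, demo="primaryid$sex$sex\n101$F$F\n")
    with pytest.raises(IngestError, match="duplicate header"):
        read_faers_ascii(paths)


def test_record_count_is_conserved(tmp_path):
    demo = DEMO + "$$$$$$$$\n103$103$20200801$$$$F$$US\n"
    paths = _write_quarter(tmp_path, demo=demo)
    result = read_faers_ascii(paths)
    log = result.log.counters
    assert log["n_cases_in"] == log["n_reports_out"] + log["n_rejected"]
    assert log["n_rejected"] == 1  # the blank-id row


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def test_interchange_round_trip_is_exact(tmp_path):
    sim = generate(SimConfig(n_reports=50, seed=7, typo_prob=0.2))
    path = tmp_path / "reports.csv"
    write_interchange_csv(sim.reports, path)
    back = read_interchange_csv(path).reports
    assert back == sim.reports


def test_invalid_interchange_date_is_missing_and_counted(tmp_path, make_report):
    r = make_report(drugs=["bevacizumab"], reactions=["Hypertension"])
    path = tmp_path / "one.csv"
    write_interchange_csv([r], path)
    text = path.read_text().replace("2020-06-01", "2020-02-30")
    path.write_text(text)
    result = read_interchange_csv(path)
    assert result.reports[0].receipt_date is None
    assert result.log.counters["bad_receipt_date"] == 1


def test_interchange_sex_token_map(tmp_path, make_report):
    r = make_report()
    path = tmp_path / "one.csv"
    write_interchange_csv([r], path)
    path.write_text(path.read_text().replace("unknown,unknown", "M,unknown"))
    assert read_interchange_csv(path).reports[0].patient_sex is Sex.MALE
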