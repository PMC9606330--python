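import datetime

import pytest

from vigisig.model import (
    DrugEntry,
    DrugRole,
    Outcome,
    PartialDate,
    SafetyReport,
    Sex,
)


@pytest.fixture
def make_report():
    """Factory for compact test reports.

    ``drugs`` is a list of ingredient names (mapped, primary suspect) or
    (name, role) tuples; ``reactions`` a list of PT strings.
    """

    counter = {"n": 0}

    def _make(
        drugs=(),
        reactions=(),
        report_id=None,
        receipt="2020-06-01",
        sex=Sex.UNKNOWN,
        age=None,
        country="US",
        outcomes=(),
        event_date=None,
        **kwargs,
    ):
        counter["n"] += 1
        entries = []
        for d in drugs:
            if isinstance(d, DrugEntry):
                entries.append(d)
                continue
            name, role = d if isinstance(d, tuple) else (d, DrugRole.PRIMARY_SUSPECT)
            entries.append(
                DrugEntry(verbatim_name=name, role=role, ingredient=name)
            )
        return SafetyReport(
            report_id=report_id or f"T{counter['n']:05d}",
            receipt_date=PartialDate(datetime.date.fromisoformat(receipt)),
            patient_sex=sex,
            patient_age_years=age,
            country=country,
            event_date=event_date,
            drugs=entries,
            reactions=list(reactions),
            outcomes=set(outcomes),
            **kwargs,
        )

    return _make
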