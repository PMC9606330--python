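#!/usr/bin/env python
"""Two-step cleaning of the raw stream.

Keeps the last version of each report id, then removes reports identical
on the six-field key (sex, age, reporter country, receipt date, reaction
PTs, verbatim drug names).  Writes the cleaned stream to scratch/ and
the removal counts to results/dedup_log.json.
"""

import json
from pathlib import Path

from vigisig.dedup import deduplicate
from vigisig.ingest import read_interchange_csv, write_interchange_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    reports = read_interchange_csv(ROOT / "scratch" / "raw_reports.csv").reports
    clean, log = deduplicate(reports)
    write_interchange_csv(clean, ROOT / "scratch" / "clean_reports.csv")
    (ROOT / "results" / "dedup_log.json").write_text(
        json.dumps(log.as_dict(), indent=2), encoding="utf-8"
    )
    print(f"read {log.n_in:,} records")
    print(f"removed {log.versions_removed:,} superseded versions, "
          f"then {log.duplicates_removed:,} six-field duplicates")
    print(f"{log.n_after_duplicates:,} cleaned reports remain")


if __name__ == "__main__":
    main()
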