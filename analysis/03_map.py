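#!/usr/bin/env python
"""Vocabulary normalization of the cleaned stream.

Maps verbatim product names (brands, research codes, injected typos)
onto ingredients with fuzzy matching enabled, using the archive implied
by the generator's catalog, and reports how many entries mapped.
"""

import json
from pathlib import Path

from vigisig.ingest import read_interchange_csv, write_interchange_csv
from vigisig.synthetic import archive_from_sidecar
from vigisig.vocab import map_reports

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    reports = read_interchange_csv(ROOT / "scratch" / "clean_reports.csv").reports
    sidecar = json.loads((ROOT / "scratch" / "sim_truth.json").read_text())
    archive = archive_from_sidecar(sidecar)
    _, counters = map_reports(reports, archive, fuzzy=True)
    write_interchange_csv(reports, ROOT / "scratch" / "mapped_reports.csv")
    (ROOT / "results" / "mapping_counts.json").write_text(
        json.dumps(counters, indent=2), encoding="utf-8"
    )
    print(f"mapped {counters['mapped']:,} drug entries, "
          f"{counters['unmapped']:,} left unmapped "
          f"(fuzzy matching recovers single-character typos)")


if __name__ == "__main__":
    main()
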