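#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emits a FAERS-like stream of 100,000 base reports (plus versioned
resubmissions and duplicate submissions) with three planted drug-event
reporting-ratio multipliers and two planted onset profiles (hypertension
short at a 23-day median, venous thromboembolism long at 51 days).  The
raw stream goes to scratch/ (it is bulky); the ground-truth sidecar and
a small summary go to results/.
"""

import json
from pathlib import Path

from vigisig.ingest import write_interchange_csv
from vigisig.synthetic import SimConfig, generate

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 20140101  # the study window's opening day, fixed once


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = SimConfig(seed=SEED)
    sim = generate(cfg)
    write_interchange_csv(sim.reports, SCRATCH / "raw_reports.csv")
    (SCRATCH / "sim_truth.json").write_text(
        json.dumps(sim.sidecar, indent=2), encoding="utf-8"
    )
    print(f"emitted {len(sim.reports):,} raw records "
          f"({sim.sidecar['n_base_reports']:,} base reports, "
          f"{len(sim.sidecar['versioned_ids']):,} versioned, "
          f"{len(sim.sidecar['duplicate_pairs']):,} duplicated)")
    print(f"planted reporting-ratio multipliers: {sim.sidecar['lambda']}")
    print(f"wrote {SCRATCH / 'raw_reports.csv'} and {SCRATCH / 'sim_truth.json'}")


if __name__ == "__main__":
    main()
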