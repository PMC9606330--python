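#!/usr/bin/env python
"""Time-to-onset and outcome-severity summaries for the signalled groups.

Summarizes onset days (median, IQR, 30/90-day cumulative proportions)
for each planted drug-event pair and tabulates outcome severity per SMQ
group.  Writes results/tto.csv and results/outcomes.csv.
"""

import json
from pathlib import Path

import pandas as pd

from vigisig.ingest import read_interchange_csv
from vigisig.model import SUSPECT_ROLES
from vigisig.outcomes import outcome_table
from vigisig.signal_stats import pt_predicate, smq_predicate
from vigisig.synthetic import archive_from_sidecar, smq_definitions_from_sidecar
from vigisig.tto import collect_tto, summarize_tto
from vigisig.vocab import resolve_drug_spec

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    reports = read_interchange_csv(ROOT / "scratch" / "mapped_reports.csv").reports
    sidecar = json.loads((ROOT / "scratch" / "sim_truth.json").read_text())
    archive = archive_from_sidecar(sidecar)
    smq_defs = smq_definitions_from_sidecar(sidecar)

    rows = []
    for key, (median_true, sigma) in sidecar["tto"].items():
        ing, pt = key.split("|")
        records, excluded = collect_tto(reports, {ing}, pt_predicate([pt]), pt)
        if not records:
            continue
        s = summarize_tto(records, excluded)
        rows.append(
            {
                "pair": key,
                "median_days_true": median_true,
                "median_days": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "pct_30d": s.pct_30d,
                "pct_90d": s.pct_90d,
                "n_included": s.n,
                "n_excluded": sum(s.exclusions.values()),
            }
        )
    tto_df = pd.DataFrame(rows)
    tto_df.to_csv(ROOT / "results" / "tto.csv", index=False)
    print("time to onset per planted pair (planted medians 23 and 51 days):")
    print(tto_df.to_string(index=False))

    target = resolve_drug_spec("class:mAb", archive) | resolve_drug_spec(
        "class:TKI", archive
    )
    groups = {}
    for code, d in sorted(smq_defs.items()):
        if not d.member_pts:
            continue
        pred = smq_predicate(code, smq_defs)
        groups[f"{d.smq_name} (SMQ)"] = [
            r for r in reports if r.ingredients(SUSPECT_ROLES) & target and pred(r)
        ]
    out_df = outcome_table(groups)
    out_df.to_csv(ROOT / "results" / "outcomes.csv", index=False)
    print("\noutcome severity per SMQ group (percent of reports):")
    print(out_df[["group", "n", "death", "life_threatening", "hospitalization", "death_lt_pct"]].to_string(index=False))


if __name__ == "__main__":
    main()
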