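"""End-to-end study orchestration and publication-style table rendering.

A study config (YAML or dict) names the input (a CSV interchange file or
a synthetic-generation block), the vocabularies, the role filter and the
analysis panels.  :func:`run_study` runs ingest -> dedup -> map ->
panels -> time-to-onset -> outcomes, logging counts at every stage in a
flowchart-style JSON, and writes the result tables.  Reruns on the same
inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import synthetic
from .dedup import deduplicate
from .ingest import read_interchange_csv, write_interchange_csv
from .model import ALL_ROLES, DrugRole, SUSPECT_ROLES
from .outcomes import outcome_table
from .signal_stats import (
    Analysis,
    ShrinkageConfig,
    SignalEstimate,
    round_half_away,
    run_panel,
    smq_predicate,
)
from .tto import collect_tto, summarize_tto
from .vocab import (
    DrugArchive,
    bundled_archive,
    bundled_smq_headers,
    load_smq_csv,
    map_reports,
    resolve_drug_spec,
)


class StudyError(Exception):
    """A stage failed; the message names the stage and the context."""


@dataclasses.dataclass
class StudyBundle:
    """Everything one run produced, before rendering."""

    flowchart: dict[str, Any]
    signals: list[SignalEstimate]
    tto: pd.DataFrame
    outcomes: pd.DataFrame
    config: dict[str, Any]  # defaults echoed back for provenance


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name."""

    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StudyError):
                raise StudyError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Guard()


def run_study(config: dict | str | Path, out_dir: str | Path | None = None) -> StudyBundle:
    """Run the full pipeline per the config; optionally write the bundle.

    Config keys (all with defaults echoed into the bundle):

    * ``input_csv`` — interchange CSV, or ``simulate`` — kwargs for
      :class:`vigisig.synthetic.SimConfig`;
    * ``drug_archive`` — CSV path or ``"bundled"``;
    * ``smq_file`` — SMQ CSV path (headers bundled if omitted);
    * ``role_filter`` — ``"suspect"`` (default) or ``"all"``;
    * ``min_reports``, ``shrinkage_k``, ``fuzzy``;
    * ``panels`` — list of {name, drug, event} where event is
      ``"smq:CODE"`` or ``"pt:NAME"``;
    * ``tto_groups`` / ``outcome_groups`` — list of {name, drug, event}.
    """
    cfg = _load_config(config)
    role_filter = SUSPECT_ROLES if cfg.get("role_filter", "suspect") == "suspect" else ALL_ROLES
    stats_cfg = ShrinkageConfig(
        shrinkage_k=float(cfg.get("shrinkage_k", 0.5)),
        min_reports=int(cfg.get("min_reports", 3)),
    )
    flowchart: dict[str, Any] = {"stages": {}}

    with _stage("ingest"):
        sidecar = None
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"])
            sim = synthetic.generate(synthetic.SimConfig(**sim_kwargs))
            reports, sidecar = sim.reports, sim.sidecar
        elif "input_csv" in cfg:
            reports = read_interchange_csv(cfg["input_csv"]).reports
        else:
            raise StudyError("stage 'ingest' failed: config needs input_csv or simulate")
        flowchart["stages"]["total_read"] = len(reports)

    with _stage("dedup"):
        clean, dedup_log = deduplicate(reports)
        flowchart["stages"]["after_last_version"] = dedup_log.n_after_versions
        flowchart["stages"]["after_dedup"] = dedup_log.n_after_duplicates
        flowchart["dedup"] = dedup_log.as_dict()

    with _stage("map"):
        archive_spec = cfg.get("drug_archive", "bundled")
        if archive_spec == "bundled":
            archive = (
                synthetic.archive_from_sidecar(sidecar)
                if sidecar is not None
                else bundled_archive()
            )
        else:
            archive = DrugArchive.from_csv(archive_spec)
        smq_defs = (
            load_smq_csv(cfg["smq_file"]) if "smq_file" in cfg else _smq_from_sidecar(sidecar)
        )
        map_reports(clean, archive, fuzzy=bool(cfg.get("fuzzy", False)))
        target = resolve_drug_spec(cfg.get("target_drugs", "class:mAb"), archive) | resolve_drug_spec(
            cfg.get("target_drugs_2", "class:TKI"), archive
        )
        n_target = sum(1 for r in clean if r.ingredients(role_filter) & target)
        flowchart["stages"]["target_drug_reports"] = n_target
        if smq_defs:
            event_codes = [c for c, d in smq_defs.items() if d.member_pts]
            seen = set()
            for code in event_codes:
                pred = smq_predicate(code, smq_defs)
                seen |= {i for i, r in enumerate(clean) if pred(r)}
            flowchart["stages"]["event_reports"] = len(seen)

    with _stage("panels"):
        analyses = [
            Analysis(p["name"], p["drug"], _parse_event(p["event"]))
            for p in cfg.get("panels", [])
        ]
        signals = (
            run_panel(clean, analyses, archive, smq_defs, stats_cfg, role_filter)
            if analyses
            else []
        )

    with _stage("tto"):
        tto_rows = []
        for grp in cfg.get("tto_groups", []):
            drugs = resolve_drug_spec(grp["drug"], archive)
            pred = _event_predicate(_parse_event(grp["event"]), smq_defs)
            records, excluded = collect_tto(clean, drugs, pred, grp["name"])
            if records:
                s = summarize_tto(records, excluded)
                tto_rows.append(
                    {
                        "group": grp["name"],
                        "n_included": s.n,
                        "median": s.median,
                        "q1": s.q1,
                        "q3": s.q3,
                        "pct_30d": s.pct_30d,
                        "pct_90d": s.pct_90d,
                        **{f"excl_{k}": v for k, v in s.exclusions.items()},
                    }
                )
        tto_df = pd.DataFrame(tto_rows)

    with _stage("outcomes"):
        groups = {}
        for grp in cfg.get("outcome_groups", []):
            drugs = resolve_drug_spec(grp["drug"], archive)
            pred = _event_predicate(_parse_event(grp["event"]), smq_defs)
            groups[grp["name"]] = [
                r for r in clean if r.ingredients(role_filter) & drugs and pred(r)
            ]
        outcomes_df = (
            outcome_table(groups, denominator=cfg.get("outcome_denominator", "all"))
            if groups
            else pd.DataFrame()
        )

    bundle = StudyBundle(
        flowchart=flowchart,
        signals=signals,
        tto=tto_df,
        outcomes=outcomes_df,
        config={
            "role_filter": "suspect" if role_filter == SUSPECT_ROLES else "all",
            "shrinkage_k": stats_cfg.shrinkage_k,
            "min_reports": stats_cfg.min_reports,
            "fuzzy": bool(cfg.get("fuzzy", False)),
            **{k: v for k, v in cfg.items() if k != "simulate"},
        },
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _parse_event(token: str) -> tuple:
    kind, _, value = token.partition(":")
    if kind == "smq":
        return ("smq", int(value))
    if kind == "pt":
        return ("pt", value)
    raise StudyError(f"stage 'config' failed: unparseable event spec {token!r}")


def _event_predicate(spec: tuple, smq_defs):
    from .signal_stats import _resolve_event_spec

    return _resolve_event_spec(spec, smq_defs)


def _smq_from_sidecar(sidecar: Optional[dict]):
    """Build SMQ definitions from a generator sidecar's event catalog."""
    if sidecar is None:
        return bundled_smq_headers()
    return synthetic.smq_definitions_from_sidecar(sidecar)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def format_n_pct(n: int, total: int) -> str:
    """Publication-style "23,177 (32.8)" with a thousands separator."""
    pct = round_half_away(100.0 * n / total, 1)
    return f"{n:,} ({pct:.1f})"


def signals_frame(signals: list[SignalEstimate], rounded: bool = True) -> pd.DataFrame:
    """Signal estimates as a table mirroring the publication layout:
    analysis, N, ROR, ROR025, ROR975, IC, IC025, IC975, signal."""
    r2 = (lambda x: round_half_away(x, 2)) if rounded else (lambda x: x)
    rows = []
    for e in signals:
        rows.append(
            {
                "analysis": e.name,
                "N": e.n_observed,
                "ROR": r2(e.ror_shrunk),
                "ROR025": r2(e.ror_ci_low) if e.ror_ci_low is not None else None,
                "ROR975": r2(e.ror_ci_high) if e.ror_ci_high is not None else None,
                "IC": r2(e.ic),
                "IC025": r2(e.ic_low),
                "IC975": r2(e.ic_high),
                "signal": e.is_signal,
            }
        )
    return pd.DataFrame(rows)


def render_tables(bundle: StudyBundle) -> dict[str, pd.DataFrame]:
    """Formatted tables (2-dp statistics, N (%) columns)."""
    sig = signals_frame(bundle.signals, rounded=True)
    if not sig.empty:
        total = int(sig["N"].sum())
        sig.insert(2, "N (%)", [format_n_pct(int(n), total) for n in sig["N"]])
    return {"signals": sig, "tto": bundle.tto, "outcomes": bundle.outcomes}


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "flowchart.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"flowchart": bundle.flowchart, "config": _jsonable(bundle.config)},
            fh,
            indent=2,
            sort_keys=True,
        )
    signals_frame(bundle.signals).to_csv(out / "signals.csv", index=False)
    bundle.tto.to_csv(out / "tto.csv", index=False)
    bundle.outcomes.to_csv(out / "outcomes.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
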