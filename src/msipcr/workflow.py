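"""End-to-end orchestration: config, pipeline runs, summaries, reports.

``run_pipeline`` ties the chain together: simulate (or load) paired lanes,
size every lane against its alignment markers, call markers tumour-vs-normal
with two-tier escalation, then summarize — cohort status table, LOD table for
dilution runs, and the MSI-PCR x IHC concordance report when IHC labels are
present.  All randomness flows from one top-level seed; per-lane streams are
derived by stable hashing, so outputs are byte-reproducible for a fixed
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cesim, lod as lod_mod
from ._stats import percent
from .cesim import GelModel, IHCErrorModel, Trace, simulate_case, simulate_cohort
from .concordance import concordance_report, dichotomize_ihc
from .msi_caller import CallerParams, SampleResult, run_two_tier
from .panel import MarkerSpec, default_panel, validate_panel
from .sizing import analyze_lane
from .traceio import peaks_to_frame, read_traces, write_traces, write_truth_sidecar

__all__ = [
    "RunConfig",
    "RunSummary",
    "ConfigError",
    "run_pipeline",
    "tier1_resolution_percent",
    "summarize_statuses",
]


class ConfigError(ValueError):
    """Invalid configuration; raised before any output is produced."""


@dataclass
class RunConfig:
    """Everything a run needs: panel, gels, thresholds, sizes, seed, paths."""

    markers: list[MarkerSpec] = field(default_factory=default_panel)
    gel_screening: GelModel = field(default_factory=GelModel.screening)
    gel_highres: GelModel = field(default_factory=GelModel.highres)
    caller: CallerParams = field(default_factory=CallerParams)
    lod_fractions: tuple[float, ...] = cesim.DEFAULT_FRACTIONS
    seed: int = 0
    cohort_size: int = 24
    msi_h_prevalence: float = 0.12
    msi_l_prevalence: float = 0.03
    ihc_error: IHCErrorModel = field(default_factory=IHCErrorModel)
    simulate_dilution: bool = True
    dilution_deletions: dict[str, int] | None = None
    write_traces: bool = False

    def __post_init__(self) -> None:
        try:
            validate_panel(self.markers)
        except ValueError as e:
            raise ConfigError(str(e)) from e
        if self.caller.shift_threshold_bp < 1:
            raise ConfigError("shift_threshold_bp must be >= 1")
        if self.cohort_size < 1:
            raise ConfigError("cohort_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            return cls._from_dict(raw)
        except (TypeError, KeyError) as e:
            raise ConfigError(str(e)) from e

    @classmethod
    def _from_dict(cls, raw: dict) -> "RunConfig":
        kw: dict = {}
        if "markers" in raw:
            kw["markers"] = [
                MarkerSpec(m["name"], int(m["germline_size"]), tuple(m["window"]))
                for m in raw["markers"]
            ]
        for gel_key in ("gel_screening", "gel_highres"):
            if gel_key in raw:
                kw[gel_key] = GelModel(**raw[gel_key])
        if "caller" in raw:
            kw["caller"] = CallerParams(**raw["caller"])
        if "ihc_error" in raw:
            kw["ihc_error"] = IHCErrorModel(**raw["ihc_error"])
        for key in (
            "seed",
            "cohort_size",
            "msi_h_prevalence",
            "msi_l_prevalence",
            "simulate_dilution",
            "dilution_deletions",
            "write_traces",
        ):
            if key in raw:
                kw[key] = raw[key]
        if "lod_fractions" in raw:
            kw["lod_fractions"] = tuple(raw["lod_fractions"])
        return cls(**kw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunSummary:
    n_cases: int
    n_escalated: int
    tier1_resolved_percent: float
    status_counts: dict[str, int]
    msi_h_prevalence_percent: float | None
    concordance_percent: float | None = None
    lod: dict | None = None
    recovery_percent: float | None = None


def tier1_resolution_percent(n_resolved: int, n_total: int) -> float:
    """Share of cases fully resolved on the screening gel.

    Reported with the round-down convention so the stated resolution rate is
    never an overstatement of the screening tier's reach.
    """
    return percent(n_resolved, n_total, convention="floor")


def summarize_statuses(results: list[SampleResult]) -> RunSummary:
    n = len(results)
    n_esc = sum(r.escalated for r in results)
    counts: dict[str, int] = {}
    for r in results:
        counts[r.status] = counts.get(r.status, 0) + 1
    n_h = counts.get("MSI-H", 0)
    return RunSummary(
        n_cases=n,
        n_escalated=n_esc,
        tier1_resolved_percent=tier1_resolution_percent(n - n_esc, n) if n else 0.0,
        status_counts=counts,
        msi_h_prevalence_percent=percent(n_h, n) if n else None,
    )


def _results_frame(results: list[SampleResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in results],
            "status": [r.status for r in results],
            "n_unstable": [r.n_unstable for r in results],
            "escalated": [r.escalated for r in results],
        }
    )


def _case_json(r: SampleResult) -> dict:
    return {
        "case_id": r.case_id,
        "status": r.status,
        "n_unstable": r.n_unstable,
        "escalated": r.escalated,
        "flags": r.flags,
        "marker_calls": [dataclasses.asdict(c) for c in r.marker_calls],
    }


def run_pipeline(
    config: RunConfig,
    mode: str = "simulate",
    out_dir: str | Path = "msipcr_run",
    *,
    traces_path: str | Path | None = None,
    samplesheet_path: str | Path | None = None,
    ihc_path: str | Path | None = None,
) -> RunSummary:
    """Run the full workflow and write its artifact tree under ``out_dir``.

    ``simulate`` mode generates a cohort (and optionally a dilution series)
    and analyzes it; ``analyze`` mode consumes user traces plus a sample
    sheet with columns ``case_id  lane_id  role  gel_type``.  Lanes failing
    anchor QC are excluded and listed in the run log.
    """
    if mode not in ("simulate", "analyze"):
        raise ConfigError(f"unknown mode {mode!r}")
    out = Path(out_dir)
    specs = config.markers
    params = config.caller
    gel_s, gel_h = config.gel_screening, config.gel_highres

    results: list[SampleResult] = []
    excluded_lanes: list[dict] = []
    ihc_labels: dict[str, dict] = {}
    truths = []
    all_traces: list[Trace] = []

    if mode == "simulate":
        cohort = simulate_cohort(
            config.cohort_size,
            config.msi_h_prevalence,
            config.ihc_error,
            config.seed,
            msi_l_prevalence=config.msi_l_prevalence,
            gel=gel_s,
            specs=specs,
        )
        for case in cohort:
            truths.append(case.truth)
            ihc_labels[case.truth.case_id] = case.ihc
            all_traces.extend([case.normal, case.tumor])
            provider = lambda case=case: simulate_case(
                case.truth, gel_h, config.seed, specs
            )
            results.append(
                run_two_tier(
                    case.normal,
                    case.tumor,
                    provider,
                    specs,
                    gel_s,
                    gel_h,
                    params,
                    case_id=case.truth.case_id,
                )
            )
    else:
        if traces_path is None or samplesheet_path is None:
            raise ConfigError("analyze mode needs --traces and --samplesheet")
        traces = {t.lane_id: t for t in read_traces(traces_path, specs)}
        sheet = pd.read_csv(samplesheet_path, sep="\t")
        need = {"case_id", "lane_id", "role", "gel_type"}
        if not need <= set(sheet.columns):
            raise ConfigError(f"sample sheet must have columns {sorted(need)}")
        if sheet.empty:
            raise ConfigError("sample sheet is empty")
        if ihc_path is not None:
            ihc_df = pd.read_csv(ihc_path, sep="\t").set_index("case_id")
            ihc_labels = {
                str(c): {p: str(ihc_df.loc[c, p]) for p in ("mlh1", "msh2", "msh6", "pms2")}
                for c in ihc_df.index
            }
        for case_id, grp in sheet.groupby("case_id", sort=False):
            def lane(role: str, gel_type: str) -> Trace | None:
                sel = grp[(grp["role"] == role) & (grp["gel_type"] == gel_type)]
                if sel.empty:
                    return None
                return traces[str(sel["lane_id"].iloc[0])]

            n_s, t_s = lane("normal", "screening"), lane("tumor", "screening")
            if n_s is None or t_s is None:
                excluded_lanes.append(
                    {"case_id": str(case_id), "reason": "missing_screening_pair"}
                )
                continue

            def provider(case_id=case_id, grp=grp):
                n_h, t_h = lane("normal", "highres"), lane("tumor", "highres")
                if n_h is None or t_h is None:
                    raise ValueError(
                        f"{case_id}: escalation needed but no high-resolution lanes"
                    )
                return n_h, t_h

            try:
                results.append(
                    run_two_tier(
                        n_s, t_s, provider, specs, gel_s, gel_h, params,
                        case_id=str(case_id),
                    )
                )
            except ValueError as e:
                excluded_lanes.append({"case_id": str(case_id), "reason": str(e)})
        all_traces = list(traces.values())

    out.mkdir(parents=True, exist_ok=True)

    peak_frames = []
    for t in all_traces:
        an = analyze_lane(t)
        if an.qc.passed:
            peak_frames.append(peaks_to_frame(t.lane_id, an.peaks))
        else:
            excluded_lanes.append({"lane_id": t.lane_id, "reason": an.qc.reason})
    if peak_frames:
        pd.concat(peak_frames, ignore_index=True).to_csv(
            out / "peaks.tsv", sep="\t", index=False, float_format="%.4f"
        )

    _results_frame(results).to_csv(out / "cohort_status.tsv", sep="\t", index=False)
    cases_dir = out / "cases"
    cases_dir.mkdir(exist_ok=True)
    for r in results:
        (cases_dir / f"{r.case_id}.json").write_text(
            json.dumps(_case_json(r), indent=1)
        )
    if truths:
        write_truth_sidecar(truths, out / "truth.json")
    if mode == "simulate" and config.write_traces:
        write_traces(all_traces, out / "traces.tsv")

    summary = summarize_statuses(results)

    if ihc_labels:
        status = {r.case_id: r.status for r in results if r.status != "Indeterminate"}
        usable_ihc = {c: ihc_labels[c] for c in status}
        report = concordance_report(status, usable_ihc)
        summary.concordance_percent = report.percent
        (out / "concordance.json").write_text(
            json.dumps(
                {
                    "counts": report.table.counts,
                    "n": report.table.n,
                    "concordant": report.concordant,
                    "percent": report.percent,
                    "discordant_cases": report.discordant_cases,
                },
                indent=1,
            )
        )

    if mode == "simulate" and config.simulate_dilution:
        deletions = config.dilution_deletions or {
            s.name: 14 for s in specs
        }
        lod_rows = []
        lod_summary = {}
        for gel in (gel_s, gel_h):
            lods = lod_mod.simulate_and_estimate_lod(
                deletions, gel, config.seed, config.lod_fractions, specs, params
            )
            for m, r in lods.items():
                lod_rows.append(
                    {
                        "marker": m,
                        "gel_type": r.gel_type,
                        "lod_fraction": r.lod_fraction,
                        "monotone": r.monotone,
                    }
                )
                lod_summary[f"{m}:{gel.gel_type}"] = r.lod_fraction
        pd.DataFrame(lod_rows).to_csv(out / "lod.tsv", sep="\t", index=False)
        summary.lod = lod_summary

    if truths:
        truth_status = {t.case_id: t.true_status for t in truths}
        hits = sum(r.status == truth_status[r.case_id] for r in results)
        summary.recovery_percent = percent(hits, len(results)) if results else None

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "mode": mode,
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "n_cases": summary.n_cases,
                "n_escalated": summary.n_escalated,
                "tier1_resolved_percent": summary.tier1_resolved_percent,
                "excluded": excluded_lanes,
            },
            indent=1,
        )
    )
    return summary
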