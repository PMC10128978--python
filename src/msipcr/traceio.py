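"""Plain-text I/O: trace TSV, sample sheets, peak tables, truth sidecars.

Trace dialect: one row per sample point with columns
``lane_id  gel_type  role  migration  signal``; lanes are grouped by
``lane_id`` and must be stored with strictly increasing migration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cesim import CaseTruth, Trace
from .panel import MarkerSpec, default_panel
from .sizing import Peak

TRACE_COLUMNS = ["lane_id", "gel_type", "role", "migration", "signal"]


def write_traces(traces: list[Trace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "lane_id": t.lane_id,
                "gel_type": t.gel_type,
                "role": t.role,
                "migration": t.migration,
                "signal": t.signal,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(
    path: str | Path, specs: list[MarkerSpec] | None = None
) -> list[Trace]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace TSV missing columns: {sorted(missing)}")
    specs = default_panel() if specs is None else specs
    traces = []
    for lane_id, grp in df.groupby("lane_id", sort=False):
        grp = grp.sort_values("migration")
        traces.append(
            Trace(
                lane_id=str(lane_id),
                gel_type=str(grp["gel_type"].iloc[0]),
                migration=grp["migration"].to_numpy(float),
                signal=np.clip(grp["signal"].to_numpy(float), 0.0, None),
                markers_expected=list(specs),
                role=str(grp["role"].iloc[0]),
            )
        )
    return traces


def peaks_to_frame(lane_id: str, peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lane_id": lane_id,
            "migration_pos": [p.migration_pos for p in peaks],
            "size_bp": [p.size_bp for p in peaks],
            "amplitude": [p.amplitude for p in peaks],
            "width_bp": [p.width_bp for p in peaks],
            "has_shoulder": [p.has_shoulder for p in peaks],
            "flags": [";".join(p.flags) for p in peaks],
        }
    )


def write_truth_sidecar(truths: list[CaseTruth], path: str | Path) -> None:
    records = [
        {
            "case_id": t.case_id,
            "unstable_markers": sorted(t.unstable_markers),
            "deletion_bp": {k: int(v) for k, v in t.deletion_bp.items()},
            "tumor_fraction": t.tumor_fraction,
            "true_status": t.true_status,
        }
        for t in truths
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_truth_sidecar(path: str | Path) -> list[CaseTruth]:
    records = json.loads(Path(path).read_text())
    return [
        CaseTruth(
            case_id=r["case_id"],
            unstable_markers=frozenset(r["unstable_markers"]),
            deletion_bp={k: int(v) for k, v in r["deletion_bp"].items()},
            tumor_fraction=float(r["tumor_fraction"]),
        )
        for r in records
    ]
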