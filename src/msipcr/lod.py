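"""Limit-of-detection estimation from tumour-DNA titration series.

The LOD of a marker on a given gel is the smallest tumour fraction at which
the marker is still called unstable, requiring an unbroken run of unstable
calls from the pure-tumour (100%) point downward.  This is a
series-membership definition, not a fitted detection curve: the reported LOD
is always one of the titration fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cesim import (
    DEFAULT_FRACTIONS,
    GelModel,
    MarkerSpec,
    Trace,
    default_panel,
    simulate_dilution_series,
)
from .msi_caller import CallerParams, call_marker
from .sizing import analyze_lane

__all__ = [
    "DilutionResult",
    "LODResult",
    "estimate_lod",
    "compare_gels",
    "call_dilution_series",
    "simulate_and_estimate_lod",
]


@dataclass(frozen=True)
class DilutionResult:
    """Per-marker unstable flags along a titration, highest fraction first."""

    marker: str
    series: tuple[tuple[float, bool], ...]
    gel_type: str

    def __post_init__(self) -> None:
        fr = [f for f, _ in self.series]
        if any(b >= a for a, b in zip(fr, fr[1:])):
            raise ValueError("series fractions must be strictly decreasing")


@dataclass(frozen=True)
class LODResult:
    marker: str
    gel_type: str
    lod_fraction: float | None
    monotone: bool


def estimate_lod(result: DilutionResult) -> LODResult:
    """Smallest fraction with an unbroken unstable run down from 100% tumour.

    ``monotone`` is False when instability reappears below a stable point
    (the LOD is then taken on the unstable prefix only).  Depends only on the
    flag sequence, hence idempotent.
    """
    if not result.series:
        raise ValueError("series is empty")
    fractions = [f for f, _ in result.series]
    if 1.0 not in fractions:
        raise ValueError("series must include the pure-tumour (1.0) point")
    ordered = sorted(result.series, key=lambda t: -t[0])
    flags = [u for _, u in ordered]
    monotone = all(not (later and not earlier) for earlier, later in zip(flags, flags[1:]))

    lod: float | None = None
    for f, unstable in ordered:
        if not unstable:
            break
        lod = f
    return LODResult(result.marker, result.gel_type, lod, monotone)


def compare_gels(screening: LODResult, highres: LODResult) -> str:
    """Order two LODs: ``highres_better`` | ``equal`` | ``screening_better``.

    A missing LOD (never unstable) is worst.
    """
    if screening.marker != highres.marker:
        raise ValueError(
            f"marker mismatch: {screening.marker} vs {highres.marker}"
        )
    s = screening.lod_fraction if screening.lod_fraction is not None else float("inf")
    h = highres.lod_fraction if highres.lod_fraction is not None else float("inf")
    if h < s:
        return "highres_better"
    if h == s:
        return "equal"
    return "screening_better"


def call_dilution_series(
    normal: Trace,
    lanes: list[tuple[float, Trace]],
    specs: list[MarkerSpec],
    gel: GelModel,
    params: CallerParams = CallerParams(),
) -> dict[str, DilutionResult]:
    """Run the marker caller down a titration on one gel type.

    An inconclusive (smeared) marker at a fraction counts as *not* detected at
    that fraction: LOD is about unambiguous instability on this gel.
    """
    n_an = analyze_lane(normal)
    if not n_an.qc.passed:
        raise ValueError(f"normal lane failed anchor QC: {n_an.qc.reason}")
    flags: dict[str, list[tuple[float, bool]]] = {s.name: [] for s in specs}
    for f, tr in sorted(lanes, key=lambda t: -t[0]):
        t_an = analyze_lane(tr)
        if not t_an.qc.passed:
            raise ValueError(f"dilution lane {tr.lane_id} failed anchor QC")
        for s in specs:
            mc = call_marker(t_an.peaks, n_an.peaks, s, gel, params)
            flags[s.name].append((f, bool(mc.unstable and not mc.inconclusive)))
    return {
        m: DilutionResult(m, tuple(v), gel.gel_type) for m, v in flags.items()
    }


def simulate_and_estimate_lod(
    marker_deletions: dict[str, int],
    gel: GelModel,
    seed: int,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    specs: list[MarkerSpec] | None = None,
    params: CallerParams = CallerParams(),
    n_replicates: int = 1,
) -> dict[str, LODResult]:
    """Titration in silico -> caller -> LOD, per marker.

    With replicates, each fraction's flag is the modal flag across seeds
    (ties resolve to unstable).
    """
    specs = default_panel() if specs is None else specs
    votes: dict[str, dict[float, int]] = {s.name: {} for s in specs}
    for r in range(n_replicates):
        normal, lanes = simulate_dilution_series(
            marker_deletions, fractions, gel, seed + r, specs, series_id=f"dil{r}"
        )
        results = call_dilution_series(normal, lanes, specs, gel, params)
        for m, dr in results.items():
            for f, u in dr.series:
                votes[m][f] = votes[m].get(f, 0) + (1 if u else 0)
    out = {}
    for m, per_f in votes.items():
        series = tuple(
            (f, per_f[f] * 2 >= n_replicates) for f in sorted(per_f, reverse=True)
        )
        out[m] = estimate_lod(DilutionResult(m, series, gel.gel_type))
    return out
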