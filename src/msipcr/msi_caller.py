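"""Tumour-vs-normal marker calls, Bethesda classification, two-tier workflow.

The instability rule is the classic paired-lane criterion: a marker is
unstable when the major band shifts by >= 3 bp (either direction by default)
or when the tumour shows new minor bands absent from the paired normal.
Bethesda mapping: 0 unstable markers -> MSS, 1 -> MSI-L, >= 2 -> MSI-H.

Markers whose tumour-lane pattern is an inconclusive smear on the screening
gel are deferred and re-called from a high-resolution gel; calls that were
conclusive at the screening tier are never altered by tier 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

from .cesim import GelModel, Trace
from .panel import MarkerSpec
from .sizing import LaneAnalysis, Peak, analyze_lane

__all__ = [
    "CallerParams",
    "MarkerCall",
    "SampleResult",
    "NoProductError",
    "NeedsEscalationError",
    "major_band",
    "detect_smear",
    "call_marker",
    "classify_sample",
    "run_two_tier",
    "bethesda_status",
]

INDETERMINATE = "Indeterminate"


class NoProductError(ValueError):
    """No peak in a marker window: PCR failure for that marker."""


class NeedsEscalationError(ValueError):
    """classify_sample received inconclusive calls; tier-2 re-run required."""


@dataclass(frozen=True)
class CallerParams:
    """Decision thresholds of the caller.

    ``minor_rel_threshold``: a tumour peak counts as a band only above this
    fraction of the tumour major's amplitude.  ``match_tol_bp``: rounding
    tolerance when matching a tumour band against normal-lane bands, per gel.
    ``smear_width_ratio``: a major band wider than this multiple of the gel's
    nominal (stutter-broadened) band width marks the marker inconclusive.
    ``smear_dominance_ratio``: among peaks overlapping the major band, a
    second band above this fraction of the major means no dominant band.
    """

    shift_threshold_bp: int = 3
    minor_rel_threshold: float = 0.10
    match_tol_bp: dict[str, int] | None = None
    smear_width_ratio: float = 1.25
    smear_dominance_ratio: float = 0.6
    sign_agnostic: bool = True
    min_conclusive_markers: int = 4

    def match_tol(self, gel_type: str) -> int:
        tol = self.match_tol_bp or {"screening": 3, "highres": 1}
        return tol[gel_type]

    def __post_init__(self) -> None:
        if self.shift_threshold_bp < 1:
            raise ValueError("shift_threshold_bp must be >= 1")


@dataclass
class MarkerCall:
    """Result of comparing one marker between tumour and normal lanes."""

    marker: str
    normal_major_bp: int | None
    tumor_major_bp: int | None
    shift_bp: int | None
    new_minor_bands: list[float]
    unstable: bool
    inconclusive: bool
    tier: str  # screening | highres
    excluded: bool = False  # no PCR product in one of the lanes
    flags: list[str] = field(default_factory=list)


@dataclass
class SampleResult:
    case_id: str
    marker_calls: list[MarkerCall]
    n_unstable: int
    status: str  # MSS | MSI-L | MSI-H | Indeterminate
    escalated: bool
    flags: list[str] = field(default_factory=list)


def bethesda_status(n_unstable: int) -> str:
    """0 -> MSS, 1 -> MSI-L, >= 2 -> MSI-H."""
    if n_unstable < 0:
        raise ValueError("n_unstable must be >= 0")
    return "MSS" if n_unstable == 0 else ("MSI-L" if n_unstable == 1 else "MSI-H")


def _in_window(peaks: list[Peak], window: tuple[float, float]) -> list[Peak]:
    lo, hi = window
    return [p for p in peaks if p.size_bp is not None and lo <= p.size_bp < hi]


def major_band(sized_peaks: list[Peak], window: tuple[float, float]) -> Peak:
    """Highest-amplitude peak in the window; ties break toward smaller size."""
    inside = _in_window(sized_peaks, window)
    if not inside:
        raise NoProductError(f"no PCR product in window {window}")
    return max(inside, key=lambda p: (p.amplitude, -p.size_bp))


def detect_smear(
    sized_peaks: list[Peak],
    window: tuple[float, float],
    gel: GelModel,
    params: CallerParams = CallerParams(),
) -> bool:
    """Inconclusive-pattern check for one marker window.

    True when the major band is substantially broader than a clean band on
    this gel, or when no dominant band stands out among mutually *overlapping*
    peaks (well-separated near-equal bands are a resolved allele pattern, not
    a smear).
    """
    inside = _in_window(sized_peaks, window)
    if not inside:
        return False
    major = max(inside, key=lambda p: (p.amplitude, -p.size_bp))
    if major.width_bp > params.smear_width_ratio * gel.nominal_band_sigma_bp:
        return True
    overlapping = [
        p
        for p in inside
        if p is not major
        and abs(p.size_bp - major.size_bp) < 2.0 * max(p.width_bp, major.width_bp)
    ]
    if overlapping:
        second = max(p.amplitude for p in overlapping)
        if second > params.smear_dominance_ratio * major.amplitude:
            return True
    return False


def call_marker(
    tumor_peaks: list[Peak],
    normal_peaks: list[Peak],
    spec: MarkerSpec,
    gel: GelModel,
    params: CallerParams = CallerParams(),
) -> MarkerCall:
    """Apply the >=3 bp shift / new-minor-band rule to one marker."""
    window = spec.window
    tier = gel.gel_type
    try:
        n_major = major_band(normal_peaks, window)
        t_major = major_band(tumor_peaks, window)
    except NoProductError:
        return MarkerCall(
            marker=spec.name,
            normal_major_bp=None,
            tumor_major_bp=None,
            shift_bp=None,
            new_minor_bands=[],
            unstable=False,
            inconclusive=False,
            tier=tier,
            excluded=True,
            flags=["no_product"],
        )

    n_bp = int(round(n_major.size_bp))
    t_bp = int(round(t_major.size_bp))
    shift = t_bp - n_bp

    tol = params.match_tol(tier)
    normal_sizes = [
        int(round(p.size_bp)) for p in _in_window(normal_peaks, window)
    ]
    minors: list[float] = []
    for p in _in_window(tumor_peaks, window):
        if p.amplitude < params.minor_rel_threshold * t_major.amplitude:
            continue
        rounded = int(round(p.size_bp))
        if any(abs(rounded - nb) <= tol for nb in normal_sizes):
            continue
        minors.append(float(p.size_bp))

    if params.sign_agnostic:
        shifted = abs(shift) >= params.shift_threshold_bp
    else:
        shifted = -shift >= params.shift_threshold_bp
    unstable = shifted or bool(minors)

    inconclusive = detect_smear(tumor_peaks, window, gel, params)
    if inconclusive:
        unstable = False  # undefined at this tier; status deferred
    return MarkerCall(
        marker=spec.name,
        normal_major_bp=n_bp,
        tumor_major_bp=t_bp,
        shift_bp=shift,
        new_minor_bands=minors,
        unstable=unstable,
        inconclusive=inconclusive,
        tier=tier,
    )


def classify_sample(
    calls: list[MarkerCall],
    case_id: str = "",
    params: CallerParams = CallerParams(),
    *,
    escalated: bool = False,
) -> SampleResult:
    """Bethesda classification over a full, conclusive call set.

    Raises ``NeedsEscalationError`` on any inconclusive call.  Markers with no
    product are excluded from the count; if fewer than
    ``params.min_conclusive_markers`` remain, the case is Indeterminate.
    """
    if any(c.inconclusive for c in calls):
        raise NeedsEscalationError(
            f"{case_id}: inconclusive markers "
            f"{[c.marker for c in calls if c.inconclusive]}"
        )
    usable = [c for c in calls if not c.excluded]
    flags = []
    if len(usable) < len(calls):
        flags.append("marker_dropout")
    if len(usable) < params.min_conclusive_markers:
        return SampleResult(
            case_id, list(calls), 0, INDETERMINATE, escalated, flags + ["too_few_markers"]
        )
    n_unstable = sum(c.unstable for c in usable)
    return SampleResult(
        case_id, list(calls), n_unstable, bethesda_status(n_unstable), escalated, flags
    )


def _call_lane_pair(
    normal: LaneAnalysis,
    tumor: LaneAnalysis,
    specs: list[MarkerSpec],
    gel: GelModel,
    params: CallerParams,
    only: set[str] | None = None,
) -> list[MarkerCall]:
    calls = []
    for spec in specs:
        if only is not None and spec.name not in only:
            continue
        calls.append(call_marker(tumor.peaks, normal.peaks, spec, gel, params))
    return calls


def run_two_tier(
    normal_screen: Trace,
    tumor_screen: Trace,
    highres_provider: Callable[[], tuple[Trace, Trace]],
    specs: list[MarkerSpec],
    gel_screen: GelModel,
    gel_high: GelModel,
    params: CallerParams = CallerParams(),
    case_id: str = "",
) -> SampleResult:
    """Screen first; re-call only the inconclusive markers at high resolution.

    ``highres_provider`` is invoked at most once and must return the
    high-resolution (normal, tumour) trace pair for the same case.  Markers
    still inconclusive at tier 2 leave the case Indeterminate (no forced
    status).
    """
    n_an = analyze_lane(normal_screen)
    t_an = analyze_lane(tumor_screen)
    if not (n_an.qc.passed and t_an.qc.passed):
        raise ValueError(
            f"{case_id}: screening lanes failed anchor QC "
            f"({n_an.qc.reason or t_an.qc.reason})"
        )
    calls = {
        c.marker: c
        for c in _call_lane_pair(n_an, t_an, specs, gel_screen, params)
    }
    pending = {m for m, c in calls.items() if c.inconclusive}
    escalated = bool(pending)
    if pending:
        hr_normal, hr_tumor = highres_provider()
        hn_an = analyze_lane(hr_normal)
        ht_an = analyze_lane(hr_tumor)
        if not (hn_an.qc.passed and ht_an.qc.passed):
            raise ValueError(f"{case_id}: high-resolution lanes failed anchor QC")
        for c in _call_lane_pair(hn_an, ht_an, specs, gel_high, params, only=pending):
            calls[c.marker] = c

    ordered = [calls[s.name] for s in specs if s.name in calls]
    still = [c.marker for c in ordered if c.inconclusive]
    if still:
        return SampleResult(
            case_id,
            ordered,
            0,
            INDETERMINATE,
            escalated,
            [f"inconclusive_after_highres:{','.join(still)}"],
        )
    return classify_sample(ordered, case_id, params, escalated=escalated)
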