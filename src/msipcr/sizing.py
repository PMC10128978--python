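"""Peak detection, alignment-marker QC and two-anchor size calibration.

Each lane is read like the instrument software reads a gel image: find band
apexes, verify that the 15 bp and 1000 bp alignment markers each appear as a
single peak with no shoulder, fit the log-linear mobility model through the
two anchors, and report calibrated sizes for every band.  Because both anchors
ride the same lane, any affine migration distortion cancels exactly.

Width convention: ``width_bp`` is the Gaussian sigma-equivalent width
(FWHM / 2.3548), so a clean band on a gel of sigma ``s`` measures ~``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, peak_widths

from .cesim import GelModel, Trace, canonical_migration, _K
from .panel import ANCHOR_HIGH_BP, ANCHOR_LOW_BP

__all__ = [
    "Peak",
    "CalibrationModel",
    "QCVerdict",
    "CalibrationError",
    "detect_peaks",
    "check_alignment_markers",
    "fit_calibration",
    "size_peaks",
    "analyze_lane",
    "LaneAnalysis",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM

#: default gel sigma used for bp-equivalent peak separation when detecting
_GEL_SIGMA_DEFAULT = {"screening": 6.0, "highres": 0.75}


class CalibrationError(ValueError):
    """Raised when a lane cannot be calibrated (degenerate or failed QC)."""


@dataclass
class Peak:
    """A detected band apex.

    ``size_bp``/``width_bp`` are populated by :func:`size_peaks`; before
    calibration only migration-domain quantities are exact (``width_bp`` holds
    a provisional value from the canonical mobility map).
    """

    migration_pos: float
    amplitude: float
    width_mig: float  # sigma-equivalent width on the migration axis
    width_bp: float
    has_shoulder: bool = False
    size_bp: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.width_mig <= 0 or self.width_bp <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reason: str | None = None  # missing_anchor | multiple_anchor_peaks | anchor_shoulder
    detail: str = ""

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


@dataclass(frozen=True)
class CalibrationModel:
    """Log-linear two-anchor map ``size(m) = exp(a + b * m)``.

    Interpolates exactly through (anchor_low_pos, 15 bp) and
    (anchor_high_pos, 1000 bp) and is strictly monotone between them.
    """

    anchor_low_pos: float
    anchor_high_pos: float
    a: float
    b: float

    def size_at(self, m: np.ndarray | float) -> np.ndarray | float:
        return np.exp(self.a + self.b * np.asarray(m, dtype=float))

    def bp_per_migration(self, m: np.ndarray | float) -> np.ndarray | float:
        """Local slope d(size)/d(migration) at position ``m``."""
        return self.b * self.size_at(m)

    def in_range(self, m: float) -> bool:
        return self.anchor_low_pos <= m <= self.anchor_high_pos


def _refine_apex(log_s: np.ndarray, i: int) -> float:
    """Sub-sample apex via a parabola through 3 log-signal points.

    Exact for a Gaussian band sampled on a locally-linear migration/size map.
    """
    if i <= 0 or i >= log_s.size - 1:
        return float(i)
    y0, y1, y2 = log_s[i - 1], log_s[i], log_s[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid apex
        return float(i)
    return float(i) + 0.5 * (y0 - y2) / denom


def _side_has_shoulder(
    d1: np.ndarray,
    apex: int,
    half_width: int,
    side: int,
    amp: float,
    sigma_samples: float,
    sigma_d1: float = 0.0,
) -> bool:
    """Detect a secondary inflection on one flank of a peak.

    On a clean flank the first derivative is single-signed and unimodal; a
    shoulder shows as an interior extremum of the derivative that does not
    reach zero (no full local minimum of the signal).  ``side`` is +1 (right)
    or -1 (left).
    """
    n = d1.size
    span = max(3, half_width)
    if side > 0:
        seg = d1[apex + 1 : min(n, apex + 1 + span)]
    else:
        seg = -d1[max(0, apex - span) : apex][::-1]
    # seg is the flank derivative oriented "descending" (expected <= 0);
    # stop at the first full minimum of the signal (derivative back above 0)
    pos = np.nonzero(seg > 0)[0]
    if pos.size:
        seg = seg[: pos[0]]
    if seg.size < 5:
        return False
    # a shoulder = the derivative recovers (local max, still < 0) and then
    # falls again by a non-trivial amount before the flank ends; the bump must
    # clear both a fraction of the peak's own maximum slope and the lane's
    # derivative noise floor
    peak_slope = 0.607 * amp / max(sigma_samples, 1.0)
    thresh = max(0.05 * peak_slope, 9.0 * sigma_d1)
    best = 0.0
    for j in range(1, seg.size - 1):
        if seg[j] >= seg[j - 1] and seg[j] > seg[j + 1] and seg[j] < 0:
            depth_before = seg[j] - seg[: j + 1].min()
            depth_after = seg[j] - seg[j:].min()
            best = max(best, min(depth_before, depth_after))
    return best > thresh


def _derivative_noise(
    signal: np.ndarray, smoothed: np.ndarray, s: float
) -> float:
    """Noise floor of the smoothed-signal derivative.

    Raw white-noise sd is estimated robustly from the smoothing residual on
    band flanks (where the zero-clip of the baseline does not rectify it) and
    propagated through the Gaussian-smooth + central-difference operators via
    their lag covariances.
    """
    active = smoothed > 0.05 * float(smoothed.max())
    resid = signal[active] - smoothed[active]
    if resid.size < 50:
        resid = signal - smoothed
    sigma_resid = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    rho0 = 1.0 / (2.0 * math.sqrt(math.pi) * s)  # Var[G*n] for unit noise
    g0 = 1.0 / (math.sqrt(2.0 * math.pi) * s)  # Cov[n, G*n]
    c_resid = math.sqrt(max(1.0 + rho0 - 2.0 * g0, 1e-12))
    rho2 = rho0 * math.exp(-4.0 / (4.0 * s * s))  # lag-2 cov of G*n
    c_d1 = math.sqrt(max((rho0 - rho2) / 2.0, 0.0))
    return sigma_resid / c_resid * c_d1


_MOMENT_CUT = 0.08  # support cutoff, fraction of apex amplitude
# second-moment of a Gaussian truncated where it falls below _MOMENT_CUT
_MOMENT_CORR = None


def _moment_correction() -> float:
    global _MOMENT_CORR
    if _MOMENT_CORR is None:
        c = math.sqrt(-2.0 * math.log(_MOMENT_CUT))
        x = np.linspace(-c, c, 4001)
        w = np.exp(-0.5 * x * x)
        var = float((w * x * x).sum() / w.sum())
        _MOMENT_CORR = math.sqrt(var)  # < 1; divide to undo truncation bias
    return _MOMENT_CORR


def _moment_width(
    smoothed: np.ndarray, apex: int, left_bound: int, right_bound: int
) -> float:
    """Sigma-equivalent width from the second moment of the band's support.

    The support is the contiguous region around the apex above a fixed
    fraction of the apex amplitude (bounded midway toward neighbouring
    peaks), so unresolved satellites and stutter mass widen the estimate —
    unlike a half-maximum width, which ignores anything below half height.
    """
    cut = _MOMENT_CUT * smoothed[apex]
    lo = apex
    while lo > left_bound and smoothed[lo - 1] >= cut:
        lo -= 1
    hi = apex
    while hi < right_bound and smoothed[hi + 1] >= cut:
        hi += 1
    if hi - lo < 2:
        return 0.0
    x = np.arange(lo, hi + 1, dtype=float)
    w = smoothed[lo : hi + 1]
    mu = float((w * x).sum() / w.sum())
    var = float((w * (x - mu) ** 2).sum() / w.sum())
    return math.sqrt(max(var, 0.0)) / _moment_correction()


def detect_peaks(
    trace: Trace,
    min_prominence: float = 0.05,
    min_separation_bp: float | None = None,
    *,
    smooth_sigma_samples: float = 2.0,
) -> list[Peak]:
    """Find band apexes in a lane.

    ``min_prominence`` is a fraction of the lane's maximum signal;
    ``min_separation_bp`` (default: one gel sigma for the lane's gel type) is
    converted to a migration-sample distance at the top of the analysable size
    range, a conservative lower bound since bp-spacing widens toward small
    fragments under log-linear mobility.
    """
    if trace.signal.size == 0:
        raise ValueError("trace is empty")
    if min_separation_bp is None:
        min_separation_bp = _GEL_SIGMA_DEFAULT.get(trace.gel_type, 1.0)
    signal = trace.signal
    if not np.any(signal > 0):
        return []
    smoothed = gaussian_filter1d(signal, smooth_sigma_samples)
    step = float(np.median(np.diff(trace.migration)))
    # bp -> migration samples, evaluated at the largest expected product size
    s_ref = max(
        [s.window[1] for s in trace.markers_expected] + [ANCHOR_LOW_BP * 2]
    )
    distance = max(1, int(min_separation_bp * _K / s_ref / step))
    prominence = min_prominence * float(smoothed.max())
    idx, props = find_peaks(smoothed, prominence=prominence, distance=distance)
    if idx.size == 0:
        return []
    widths_samples = peak_widths(smoothed, idx, rel_height=0.5)[0]
    log_s = np.log(np.clip(smoothed, 1e-12, None))
    d1 = np.gradient(smoothed)
    sigma_d1 = _derivative_noise(signal, smoothed, smooth_sigma_samples)

    peaks: list[Peak] = []
    for j, i in enumerate(idx):
        apex_samples = _refine_apex(log_s, int(i))
        pos = float(np.interp(apex_samples, np.arange(signal.size), trace.migration))
        left_bound = int((idx[j - 1] + i) // 2) if j > 0 else 0
        right_bound = int((idx[j + 1] + i) // 2) if j + 1 < idx.size else signal.size - 1
        wm_samples = _moment_width(smoothed, int(i), left_bound, right_bound)
        if wm_samples <= 0:
            wm_samples = float(widths_samples[j]) / _FWHM
        width_mig = max(wm_samples * step, 1e-9)
        sigma_samples = max(widths_samples[j] / _FWHM, 1.0)
        half = max(3, int(round(2.0 * widths_samples[j])))
        amp = float(smoothed[i])
        shoulder = _side_has_shoulder(
            d1, int(i), half, +1, amp, sigma_samples, sigma_d1
        ) or _side_has_shoulder(d1, int(i), half, -1, amp, sigma_samples, sigma_d1)
        # provisional bp width from the canonical mobility slope
        s_prov = ANCHOR_LOW_BP * math.exp((pos - 100.0) / _K)
        width_bp = width_mig * s_prov / _K
        peaks.append(
            Peak(
                migration_pos=pos,
                amplitude=float(signal[i]) if signal[i] > 0 else amp,
                width_mig=width_mig,
                width_bp=max(width_bp, 1e-9),
                has_shoulder=bool(shoulder),
            )
        )
    peaks.sort(key=lambda p: p.migration_pos)
    return peaks


def _anchor_windows(trace: Trace) -> tuple[tuple[float, float], tuple[float, float]]:
    """Anchor search windows: the outer quarters of the migration axis.

    The pentaplex products (< ~300 bp) sit in the middle half of the axis
    under the instrument's mobility map, so the extreme quarters contain only
    the co-injected alignment markers.
    """
    m0, m1 = float(trace.migration[0]), float(trace.migration[-1])
    span = m1 - m0
    return (m0, m0 + 0.25 * span), (m1 - 0.25 * span, m1)


def check_alignment_markers(peaks: list[Peak], trace: Trace) -> QCVerdict:
    """Single-peak / no-shoulder QC on the 15 bp and 1000 bp anchors."""
    low_w, high_w = _anchor_windows(trace)
    for name, (lo, hi) in (("15bp", low_w), ("1000bp", high_w)):
        inside = [p for p in peaks if lo <= p.migration_pos <= hi]
        if not inside:
            return QCVerdict(False, "missing_anchor", f"no peak in {name} window")
        if len(inside) > 1:
            return QCVerdict(
                False, "multiple_anchor_peaks", f"{len(inside)} peaks in {name} window"
            )
        if inside[0].has_shoulder:
            return QCVerdict(False, "anchor_shoulder", f"{name} anchor has a shoulder")
    return QCVerdict(True)


def fit_calibration(peaks: list[Peak], trace: Trace | None = None) -> CalibrationModel:
    """Fit ``size(m) = exp(a + b m)`` exactly through the two anchor peaks.

    The anchors are taken as the extreme-migration peaks (within the anchor
    windows when ``trace`` is supplied).  Lanes failing anchor QC must not
    reach this point; a degenerate anchor pair raises ``CalibrationError``.
    """
    if trace is not None:
        verdict = check_alignment_markers(peaks, trace)
        if not verdict.passed:
            raise CalibrationError(f"anchor QC failed: {verdict.reason}")
    if len(peaks) < 2:
        raise CalibrationError("need at least two peaks to calibrate")
    ordered = sorted(peaks, key=lambda p: p.migration_pos)
    m_lo, m_hi = ordered[0].migration_pos, ordered[-1].migration_pos
    if math.isclose(m_lo, m_hi, rel_tol=0, abs_tol=1e-12):
        raise CalibrationError("anchor positions coincide; cannot calibrate")
    b = math.log(ANCHOR_HIGH_BP / ANCHOR_LOW_BP) / (m_hi - m_lo)
    a = math.log(ANCHOR_LOW_BP) - b * m_lo
    return CalibrationModel(anchor_low_pos=m_lo, anchor_high_pos=m_hi, a=a, b=b)


def size_peaks(peaks: list[Peak], model: CalibrationModel) -> list[Peak]:
    """Populate calibrated ``size_bp`` (and exact ``width_bp``) on each peak."""
    sized: list[Peak] = []
    for p in peaks:
        size = float(model.size_at(p.migration_pos))
        width_bp = float(p.width_mig * model.bp_per_migration(p.migration_pos))
        flags = list(p.flags)
        if not model.in_range(p.migration_pos):
            flags = flags + ["out_of_range"]
        sized.append(
            replace(p, size_bp=size, width_bp=max(width_bp, 1e-9), flags=flags)
        )
    return sized


@dataclass
class LaneAnalysis:
    trace: Trace
    qc: QCVerdict
    peaks: list[Peak]  # sized; empty when QC failed
    model: CalibrationModel | None


def analyze_lane(
    trace: Trace,
    min_prominence: float = 0.05,
    min_separation_bp: float | None = None,
) -> LaneAnalysis:
    """Detect -> QC -> calibrate -> size one lane; no sizes when QC fails."""
    raw = detect_peaks(trace, min_prominence, min_separation_bp)
    qc = check_alignment_markers(raw, trace)
    if not qc.passed:
        return LaneAnalysis(trace, qc, [], None)
    model = fit_calibration(raw)
    return LaneAnalysis(trace, qc, size_peaks(raw, model), model)
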