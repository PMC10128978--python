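"""Synthetic capillary-electrophoresis electropherogram generator.

Emulates the statistical structure of a non-labeled CE MSI-PCR run: each lane
carries the 15 bp and 1000 bp alignment-marker peaks, one Gaussian band per
allele of each pentaplex marker, a contraction-side stutter ladder, additive
baseline noise, and a per-lane affine migration distortion.  Tumour lanes mix
germline and somatically deleted alleles at a configurable tumour fraction,
which is how dilution (titration) series and cohorts with known ground truth
are produced.

Migration physics: the instrument convention is a log-linear mobility map
``migration = M0 + K * ln(size / 15)`` (so the two anchors sit at fixed
canonical positions), composed with a per-lane affine distortion.  This is the
exact inverse of the two-anchor calibration fitted by :mod:`msipcr.sizing`, so
noise-free round-trips are exact up to grid interpolation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .panel import (
    ANCHOR_HIGH_BP,
    ANCHOR_LOW_BP,
    MarkerSpec,
    default_panel,
    marker_by_name,
    validate_panel,
)

__all__ = [
    "MarkerSpec",
    "GelModel",
    "CaseTruth",
    "Trace",
    "LaneDistortion",
    "IHCErrorModel",
    "CohortCase",
    "size_to_migration",
    "migration_to_size",
    "simulate_lane",
    "simulate_case",
    "simulate_dilution_series",
    "simulate_cohort",
    "DEFAULT_FRACTIONS",
    "DEFAULT_DELETION_RANGE",
]

# Canonical (distortion-free) anchor positions on the migration axis.
MIG_LOW_ANCHOR = 100.0
MIG_HIGH_ANCHOR = 900.0
_K = (MIG_HIGH_ANCHOR - MIG_LOW_ANCHOR) / math.log(ANCHOR_HIGH_BP / ANCHOR_LOW_BP)

#: HCT116-style titration points: tumour-DNA fraction of the input mix.
DEFAULT_FRACTIONS = (1.0, 0.5, 0.2, 0.1, 0.075, 0.05, 0.025)

#: Somatic deletions at these poly-A loci are predominantly >10 bp.
DEFAULT_DELETION_RANGE = (11, 16)

_GRID_START = 0.0
_GRID_STOP = 1024.0
_GRID_STEP = 0.1

_AMP_GERMLINE = 1000.0
_AMP_ANCHOR = 1500.0


@dataclass(frozen=True)
class LaneDistortion:
    """Affine per-lane migration distortion ``m' = scale * m + offset``."""

    scale: float = 1.0
    offset: float = 0.0

    def apply(self, m: np.ndarray | float) -> np.ndarray | float:
        return self.scale * m + self.offset

    def invert(self, m: np.ndarray | float) -> np.ndarray | float:
        return (m - self.offset) / self.scale


IDENTITY = LaneDistortion()


@dataclass(frozen=True)
class GelModel:
    """Resolution and noise model of one QIAxcel gel cartridge type.

    ``peak_sigma_bp`` is the Gaussian band standard deviation in bp; two
    equal-amplitude bands are resolvable (bimodal) iff separated by more than
    ``2 * peak_sigma_bp``, so the defaults put screening-gel resolvability at
    12 bp (in the instrument's 10-15 bp class) and high-resolution at 1.5 bp
    (1-3 bp class).  Stutter is contraction-only: satellites at -1..-steps bp
    with geometrically decaying amplitude.
    """

    gel_type: str  # "screening" | "highres"
    peak_sigma_bp: float
    noise_sd: float
    stutter_decay: float = 0.5
    stutter_steps: int = 3

    def __post_init__(self) -> None:
        if self.gel_type not in ("screening", "highres"):
            raise ValueError(f"unknown gel_type {self.gel_type!r}")
        if self.peak_sigma_bp <= 0:
            raise ValueError("peak_sigma_bp must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.stutter_decay < 1:
            raise ValueError("stutter_decay must be in [0, 1)")
        if self.stutter_steps < 0:
            raise ValueError("stutter_steps must be nonnegative")

    @classmethod
    def screening(cls, **kw) -> "GelModel":
        return cls("screening", peak_sigma_bp=6.0, noise_sd=12.0, **kw)

    @classmethod
    def highres(cls, **kw) -> "GelModel":
        return cls("highres", peak_sigma_bp=0.75, noise_sd=8.0, **kw)

    @property
    def nominal_band_sigma_bp(self) -> float:
        """Sigma-equivalent width of a clean single-allele band with stutter.

        The merged allele + stutter family behaves like a band of variance
        ``peak_sigma^2 + Var(stutter offsets)`` with geometric weights; this is
        the width a non-smeared band is expected to show on this gel.
        """
        if self.stutter_steps == 0 or self.stutter_decay == 0:
            return self.peak_sigma_bp
        k = np.arange(0, self.stutter_steps + 1, dtype=float)
        w = self.stutter_decay**k
        w /= w.sum()
        mean = float((w * -k).sum())
        var = float((w * k**2).sum() - mean**2)
        return math.sqrt(self.peak_sigma_bp**2 + var)


@dataclass(frozen=True)
class CaseTruth:
    """Ground truth for one simulated tumour/normal pair."""

    case_id: str
    unstable_markers: frozenset[str]
    deletion_bp: dict[str, int]
    tumor_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        missing = set(self.unstable_markers) - set(self.deletion_bp)
        if missing:
            raise ValueError(f"no deletion length for unstable markers {missing}")
        for m, d in self.deletion_bp.items():
            if d <= 0:
                raise ValueError(f"deletion_bp[{m}] must be positive")

    @property
    def true_status(self) -> str:
        """Bethesda status implied by the unstable-marker count."""
        n = len(self.unstable_markers)
        return "MSS" if n == 0 else ("MSI-L" if n == 1 else "MSI-H")


@dataclass
class Trace:
    """One lane's raw electropherogram plus metadata."""

    lane_id: str
    gel_type: str
    migration: np.ndarray
    signal: np.ndarray
    markers_expected: list[MarkerSpec] = field(default_factory=default_panel)
    role: str = "tumor"  # tumor | normal | dilution

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.migration.ndim != 1 or self.signal.shape != self.migration.shape:
            raise ValueError("migration and signal must be 1-D arrays of equal length")
        if self.migration.size and np.any(np.diff(self.migration) <= 0):
            raise ValueError("migration must be strictly increasing")
        if self.signal.size and float(self.signal.min()) < 0:
            raise ValueError("signal must be nonnegative")


def _lane_rng(seed: int, lane_id: str) -> np.random.Generator:
    # One stream per (seed, lane_id): adding lanes never perturbs existing ones.
    return np.random.default_rng([int(seed), zlib.crc32(lane_id.encode("utf-8"))])


def canonical_migration(size_bp: np.ndarray | float) -> np.ndarray | float:
    return MIG_LOW_ANCHOR + _K * np.log(np.asarray(size_bp, dtype=float) / ANCHOR_LOW_BP)


def size_to_migration(
    size_bp: float, lane_distortion: LaneDistortion = IDENTITY
) -> float:
    """Map a fragment size to its apex position on this lane's migration axis."""
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    if not 1.0 <= size_bp <= 1200.0:
        raise ValueError("size_bp must be within [1, 1200]")
    return float(lane_distortion.apply(canonical_migration(size_bp)))


def migration_to_size(
    m: np.ndarray | float, lane_distortion: LaneDistortion = IDENTITY
) -> np.ndarray | float:
    """Inverse of :func:`size_to_migration` (the simulator's own bookkeeping)."""
    canon = lane_distortion.invert(np.asarray(m, dtype=float))
    return ANCHOR_LOW_BP * np.exp((canon - MIG_LOW_ANCHOR) / _K)


def _migration_grid() -> np.ndarray:
    n = int(round((_GRID_STOP - _GRID_START) / _GRID_STEP)) + 1
    return np.linspace(_GRID_START, _GRID_STOP, n)


def simulate_lane(
    specs: list[MarkerSpec],
    allele_sizes: dict[str, list[tuple[float, float]]],
    gel: GelModel,
    lane_distortion: LaneDistortion = IDENTITY,
    seed: int = 0,
    *,
    lane_id: str = "lane",
    role: str = "tumor",
    base_amplitude: float = _AMP_GERMLINE,
    anchor_amplitude: float = _AMP_ANCHOR,
    anchor_sigma_mig: float = 2.0,
) -> Trace:
    """Render one lane: anchors + per-allele Gaussian bands + stutter + noise.

    ``allele_sizes`` maps marker name to ``[(size_bp, relative_amount), ...]``
    with amounts summing to 1 per marker.  Deterministic given ``seed`` and
    ``lane_id``.
    """
    validate_panel(specs)
    grid = _migration_grid()
    size_at = np.asarray(migration_to_size(grid, lane_distortion))
    signal = np.zeros_like(grid)

    def add_band(center_bp: float, amplitude: float) -> None:
        signal[:] += amplitude * np.exp(
            -((size_at - center_bp) ** 2) / (2.0 * gel.peak_sigma_bp**2)
        )

    # Alignment markers are crisp co-injected reference bands: fixed width on
    # the migration axis (unlike PCR products, whose width is set by the gel's
    # bp resolution at their size).
    for anchor_bp in (ANCHOR_LOW_BP, ANCHOR_HIGH_BP):
        m_anchor = float(lane_distortion.apply(canonical_migration(anchor_bp)))
        signal[:] += anchor_amplitude * np.exp(
            -((grid - m_anchor) ** 2) / (2.0 * anchor_sigma_mig**2)
        )

    for name, alleles in allele_sizes.items():
        spec = marker_by_name(specs, name)
        total = sum(a for _, a in alleles)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(
                f"{name}: relative amounts sum to {total}, expected 1"
            )
        for size_bp, amount in alleles:
            if not spec.contains(size_bp):
                raise ValueError(
                    f"{name}: allele size {size_bp} outside window {spec.window}"
                )
            if amount <= 0:
                continue
            amp = amount * base_amplitude
            add_band(size_bp, amp)
            for k in range(1, gel.stutter_steps + 1):
                add_band(size_bp - k, amp * gel.stutter_decay**k)

    if gel.noise_sd > 0:
        rng = _lane_rng(seed, lane_id)
        signal = signal + rng.normal(0.0, gel.noise_sd, size=grid.shape)
    signal = np.clip(signal, 0.0, None)
    return Trace(
        lane_id=lane_id,
        gel_type=gel.gel_type,
        migration=grid,
        signal=signal,
        markers_expected=list(specs),
        role=role,
    )


def _sample_distortion(rng: np.random.Generator) -> LaneDistortion:
    return LaneDistortion(
        scale=float(rng.uniform(0.97, 1.03)), offset=float(rng.uniform(-8.0, 8.0))
    )


def _germline_alleles(specs: list[MarkerSpec]) -> dict[str, list[tuple[float, float]]]:
    return {s.name: [(float(s.germline_size), 1.0)] for s in specs}


def _tumor_alleles(
    truth: CaseTruth, specs: list[MarkerSpec]
) -> dict[str, list[tuple[float, float]]]:
    f = truth.tumor_fraction
    alleles: dict[str, list[tuple[float, float]]] = {}
    for s in specs:
        if s.name in truth.unstable_markers and f > 0:
            deleted = float(s.germline_size - truth.deletion_bp[s.name])
            entry = [(deleted, f)]
            if f < 1:
                entry.append((float(s.germline_size), 1.0 - f))
            alleles[s.name] = entry
        else:
            alleles[s.name] = [(float(s.germline_size), 1.0)]
    return alleles


def simulate_case(
    truth: CaseTruth,
    gel: GelModel,
    seed: int = 0,
    specs: list[MarkerSpec] | None = None,
    *,
    distort: bool = True,
) -> tuple[Trace, Trace]:
    """Simulate the paired lanes of one case: (normal, tumour).

    The normal lane carries germline alleles only; for each unstable marker the
    tumour lane is a ``(1-f)`` germline / ``f`` deleted-allele mixture at the
    case's tumour fraction.  Both lanes get independent affine distortions (the
    two-anchor calibration absorbs them).
    """
    specs = default_panel() if specs is None else specs
    suffix = "_hr" if gel.gel_type == "highres" else ""
    ids = (f"{truth.case_id}_N{suffix}", f"{truth.case_id}_T{suffix}")
    traces = []
    for lane_id, alleles, role in (
        (ids[0], _germline_alleles(specs), "normal"),
        (ids[1], _tumor_alleles(truth, specs), "tumor"),
    ):
        distortion = (
            _sample_distortion(_lane_rng(seed, lane_id + "/distortion"))
            if distort
            else IDENTITY
        )
        traces.append(
            simulate_lane(
                specs,
                alleles,
                gel,
                distortion,
                seed,
                lane_id=lane_id,
                role=role,
            )
        )
    return traces[0], traces[1]


def simulate_dilution_series(
    marker_deletions: dict[str, int],
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    gel: GelModel = None,
    seed: int = 0,
    specs: list[MarkerSpec] | None = None,
    *,
    series_id: str = "dil",
    distort: bool = True,
) -> tuple[Trace, list[tuple[float, Trace]]]:
    """Simulate a titration: one normal lane + one tumour lane per fraction.

    All tumour lanes share the same germline background; each lane draws its
    noise from its own (seed, lane_id)-keyed stream.
    """
    if gel is None:
        gel = GelModel.screening()
    if not fractions:
        raise ValueError("fractions must be nonempty")
    if len(set(fractions)) != len(fractions):
        raise ValueError("fractions must be distinct")
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    specs = default_panel() if specs is None else specs
    suffix = "_hr" if gel.gel_type == "highres" else ""

    normal_id = f"{series_id}_N{suffix}"
    norm_distortion = (
        _sample_distortion(_lane_rng(seed, normal_id + "/distortion"))
        if distort
        else IDENTITY
    )
    normal = simulate_lane(
        specs,
        _germline_alleles(specs),
        gel,
        norm_distortion,
        seed,
        lane_id=normal_id,
        role="normal",
    )
    lanes = []
    for f in fractions:
        truth = CaseTruth(
            case_id=f"{series_id}_{f:g}",
            unstable_markers=frozenset(marker_deletions),
            deletion_bp=dict(marker_deletions),
            tumor_fraction=f,
        )
        lane_id = f"{series_id}_T{f:g}{suffix}"
        distortion = (
            _sample_distortion(_lane_rng(seed, lane_id + "/distortion"))
            if distort
            else IDENTITY
        )
        lanes.append(
            (
                f,
                simulate_lane(
                    specs,
                    _tumor_alleles(truth, specs),
                    gel,
                    distortion,
                    seed,
                    lane_id=lane_id,
                    role="dilution",
                ),
            )
        )
    return normal, lanes


@dataclass(frozen=True)
class IHCErrorModel:
    """How simulated MMR-IHC labels deviate from the MSI ground truth.

    Exact-count mode (``false_loss_count`` / ``false_preserved_count``) perturbs
    precisely that many cases, chosen reproducibly from the cohort RNG;
    otherwise per-case Bernoulli rates apply.  ``false_loss`` cases get an
    isolated MSH6 loss (the MSH6-without-MSI discordance mode), ``false
    preserved`` cases keep all four proteins despite MSI-H truth.
    """

    false_loss_count: int | None = None
    false_preserved_count: int | None = None
    false_loss_rate: float = 0.0
    false_preserved_rate: float = 0.0


_PRESERVED = {"mlh1": "preserved", "msh2": "preserved", "msh6": "preserved", "pms2": "preserved"}


def _ihc_for_truth(status: str, rng: np.random.Generator) -> dict[str, str]:
    labels = dict(_PRESERVED)
    if status == "MSI-H":
        if rng.random() < 0.7:
            labels["mlh1"] = labels["pms2"] = "loss"
        else:
            labels["msh2"] = labels["msh6"] = "loss"
    return labels


@dataclass
class CohortCase:
    truth: CaseTruth
    normal: Trace
    tumor: Trace
    ihc: dict[str, str]


def make_case_truth(
    case_id: str,
    status: str,
    rng: np.random.Generator,
    specs: list[MarkerSpec],
    *,
    deletion_range: tuple[int, int] = DEFAULT_DELETION_RANGE,
    tumor_fraction_range: tuple[float, float] = (0.2, 1.0),
    tumor_fraction: float | None = None,
) -> CaseTruth:
    """Draw a ground-truth case of the requested Bethesda status."""
    names = [s.name for s in specs]
    if status == "MSS":
        n_unstable = 0
    elif status == "MSI-L":
        n_unstable = 1
    elif status == "MSI-H":
        # MSI-H tumours are typically unstable at most of the pentaplex.
        n_unstable = int(rng.choice([2, 3, 4, 5], p=[0.15, 0.2, 0.3, 0.35]))
    else:
        raise ValueError(f"unknown status {status!r}")
    unstable = rng.choice(names, size=n_unstable, replace=False) if n_unstable else []
    lo, hi = deletion_range
    deletions = {m: int(rng.integers(lo, hi + 1)) for m in unstable}
    if tumor_fraction is None:
        tumor_fraction = float(rng.uniform(*tumor_fraction_range))
    return CaseTruth(
        case_id=case_id,
        unstable_markers=frozenset(map(str, unstable)),
        deletion_bp=deletions,
        tumor_fraction=tumor_fraction,
    )


def simulate_cohort(
    n: int,
    msi_h_prevalence: float = 0.12,
    ihc_error_model: IHCErrorModel = IHCErrorModel(),
    seed: int = 0,
    *,
    msi_l_prevalence: float = 0.03,
    gel: GelModel | None = None,
    specs: list[MarkerSpec] | None = None,
    tumor_fraction: float | None = None,
    tumor_fraction_range: tuple[float, float] = (0.2, 1.0),
    distort: bool = True,
) -> list[CohortCase]:
    """Simulate a paired tumour/normal cohort with IHC labels.

    IHC labels are "loss" for MSI-H truth and "preserved" otherwise, then
    perturbed per ``ihc_error_model``.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= msi_h_prevalence <= 1:
        raise ValueError("msi_h_prevalence must be in [0, 1]")
    gel = GelModel.screening() if gel is None else gel
    specs = default_panel() if specs is None else specs
    rng = np.random.default_rng([int(seed), zlib.crc32(b"cohort")])

    cases: list[CohortCase] = []
    for i in range(n):
        u = rng.random()
        if u < msi_h_prevalence:
            status = "MSI-H"
        elif u < msi_h_prevalence + msi_l_prevalence:
            status = "MSI-L"
        else:
            status = "MSS"
        truth = make_case_truth(
            f"case{i:04d}",
            status,
            rng,
            specs,
            tumor_fraction=tumor_fraction,
            tumor_fraction_range=tumor_fraction_range,
        )
        normal, tumor = simulate_case(truth, gel, seed, specs, distort=distort)
        ihc = _ihc_for_truth(truth.true_status, rng)
        cases.append(CohortCase(truth, normal, tumor, ihc))

    em = ihc_error_model
    non_h = [c for c in cases if c.truth.true_status != "MSI-H"]
    msi_h = [c for c in cases if c.truth.true_status == "MSI-H"]
    if em.false_loss_count is not None or em.false_preserved_count is not None:
        k_loss = min(em.false_loss_count or 0, len(non_h))
        k_pres = min(em.false_preserved_count or 0, len(msi_h))
        for c in rng.choice(len(non_h), size=k_loss, replace=False) if k_loss else []:
            non_h[int(c)].ihc = dict(_PRESERVED, msh6="loss")
        for c in rng.choice(len(msi_h), size=k_pres, replace=False) if k_pres else []:
            msi_h[int(c)].ihc = dict(_PRESERVED)
    else:
        for c in non_h:
            if rng.random() < em.false_loss_rate:
                c.ihc = dict(_PRESERVED, msh6="loss")
        for c in msi_h:
            if rng.random() < em.false_preserved_rate:
                c.ihc = dict(_PRESERVED)
    return cases
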