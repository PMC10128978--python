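"""Mononucleotide marker panel definitions.

The assay follows the ESMO-recommended pentaplex of quasi-monomorphic poly-A
microsatellites (BAT-25, BAT-26, NR-21, NR-24, NR-27).  Germline product sizes
are laboratory configuration, not biology fixed by the assay: every call is
made relative to the paired normal lane, so any set of distinct, well-separated
windows between the two alignment markers is valid.  The defaults below keep
neighbouring germline products >= 38 bp apart so that screening-gel bands
(sigma ~6 bp) do not bleed into each other's windows, and leave >= 20 bp of
headroom below each germline size for deleted alleles plus their stutter.
"""

from __future__ import annotations

from dataclasses import dataclass

ANCHOR_LOW_BP = 15.0
ANCHOR_HIGH_BP = 1000.0

MARKER_NAMES = ("NR-27", "NR-21", "BAT-25", "NR-24", "BAT-26")


@dataclass(frozen=True)
class MarkerSpec:
    """One microsatellite marker: identity, germline product size, size window.

    ``window`` is the half-open bp interval ``[lo, hi)`` in which this marker's
    PCR products (germline and somatically contracted alleles) are expected.
    """

    name: str
    germline_size: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < self.germline_size < hi:
            raise ValueError(
                f"{self.name}: germline size {self.germline_size} not strictly "
                f"inside window [{lo}, {hi})"
            )
        if not (ANCHOR_LOW_BP < lo and hi < ANCHOR_HIGH_BP):
            raise ValueError(
                f"{self.name}: window [{lo}, {hi}) must lie strictly between "
                f"the alignment markers ({ANCHOR_LOW_BP}, {ANCHOR_HIGH_BP})"
            )

    def contains(self, size_bp: float) -> bool:
        lo, hi = self.window
        return lo <= size_bp < hi


def default_panel() -> list[MarkerSpec]:
    """The five-marker panel with the package's default size layout."""
    return [
        MarkerSpec("NR-27", 80, (58.0, 98.0)),
        MarkerSpec("NR-21", 120, (98.0, 138.0)),
        MarkerSpec("BAT-25", 160, (138.0, 178.0)),
        MarkerSpec("NR-24", 200, (178.0, 218.0)),
        MarkerSpec("BAT-26", 245, (218.0, 262.0)),
    ]


def validate_panel(specs: list[MarkerSpec]) -> None:
    """Check pairwise-disjoint windows (MarkerSpec validates the rest)."""
    ordered = sorted(specs, key=lambda s: s.window[0])
    for a, b in zip(ordered, ordered[1:]):
        if b.window[0] < a.window[1]:
            raise ValueError(
                f"marker windows overlap: {a.name} {a.window} vs {b.name} {b.window}"
            )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker names in panel")


def marker_by_name(specs: list[MarkerSpec], name: str) -> MarkerSpec:
    for s in specs:
        if s.name == name:
            return s
    raise KeyError(name)
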