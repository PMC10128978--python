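"""Small shared reporting helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def percent(k: int, n: int, decimals: int = 1, convention: str = "round") -> float:
    """``100 * k / n`` formatted to ``decimals``.

    ``convention="round"`` is half-up rounding (the usual table convention);
    ``"floor"`` truncates, i.e. never overstates the proportion — used for the
    tier-1 resolution rate in run summaries.
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    value = 100.0 * k / n
    scale = 10**decimals
    if convention == "round":
        q = Decimal(1).scaleb(-decimals)
        return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
    if convention == "floor":
        return math.floor(value * scale) / scale
    raise ValueError(f"unknown convention {convention!r}")
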