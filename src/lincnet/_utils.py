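"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so 14.05 -> 14.1, -14.05 -> -14.1).

    Python's built-in round() uses banker's rounding; reported percentages
    here follow the convention that produces 14.1% from 13/92.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numer: float, denom: float, decimals: int = 1) -> float:
    """Percentage numer/denom*100 with round-half-away display rounding."""
    if denom == 0:
        return float("nan")
    return round_half_away(100.0 * numer / denom, decimals)


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for a named stream derived from one study seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))
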