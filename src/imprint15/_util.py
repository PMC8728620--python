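"""Small shared helpers: rounding/rendering conventions and seed plumbing."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["round_half_away", "percent_str", "one_in_n_str", "spawn_rngs"]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1), unlike banker's rounding."""
    factor = 10.0**decimals
    scaled = x * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


def percent_str(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percent string, half-away-from-zero."""
    value = round_half_away(fraction * 100.0, decimals)
    return f"{value:.{decimals}f}"


def one_in_n_str(n: int) -> str:
    """Render '1 in N' with spaces grouping thousands for 5+ digit N (16579 -> '1 in 16 579')."""
    digits = str(int(n))
    if len(digits) >= 5:
        groups = []
        while digits:
            groups.append(digits[-3:])
            digits = digits[:-3]
        digits = " ".join(reversed(groups))
    return f"1 in {digits}"


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive n independent generators from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
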