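"""First-tier population screening on MS-QMA methylation ratios.

Two calling modes:

* ``sd_rule`` — the normal range is mean +/- k*SD of the screened cohort's
  own methylation-ratio distribution (k=3 by default); a sample is flagged
  when its ratio falls strictly outside that range.
* ``conservative`` — fixed bands from the validation panels: PWS band at
  ratio >= 0.88, AS band at ratio <= 0.12 (inclusive, as published).

The conservative bands are nested inside the sd_rule range, so every
conservative positive is also an sd_rule positive; the sd_rule additionally
catches intermediate-high duplication cases (an idic15 sits near 0.75-0.80,
inside the conservative normal zone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import round_half_away

__all__ = [
    "ThresholdSet",
    "Tier1Call",
    "Tier1Summary",
    "compute_thresholds",
    "conservative_thresholds",
    "call_tier1",
    "screen_cohort",
]

AS_BAND_MAX = 0.12
PWS_BAND_MIN = 0.88


@dataclass(frozen=True)
class ThresholdSet:
    mode: str  # sd_rule | conservative
    mean: float
    sd: float
    k: float
    lower: float
    upper: float
    as_band_max: float = AS_BAND_MAX
    pws_band_min: float = PWS_BAND_MIN

    def __post_init__(self) -> None:
        if self.mode not in ("sd_rule", "conservative"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError("thresholds must satisfy 0 <= lower <= upper <= 1")
        if self.mode == "conservative" and not (
            self.as_band_max < self.lower and self.pws_band_min > self.upper
        ):
            raise ValueError("conservative bands must lie outside the sd_rule range")


@dataclass(frozen=True)
class Tier1Call:
    sample_id: str
    ratio: float
    band: str  # negative | low_band | high_band

    @property
    def referred(self) -> bool:
        return self.band != "negative"


@dataclass(frozen=True)
class Tier1Summary:
    n_screened: int
    n_low: int
    n_high: int

    @property
    def n_referred(self) -> int:
        return self.n_low + self.n_high

    @property
    def percent_referred(self) -> float:
        """Referral rate in percent, rounded half-away-from-zero to 2 decimals."""
        return round_half_away(100.0 * self.n_referred / self.n_screened, 2)


def compute_thresholds(
    ratios: Sequence[float],
    k: float = 3.0,
    *,
    min_ratios: int = 100,
    robust: bool = False,
) -> ThresholdSet:
    """Normal range mean -/+ k*SD from the screened distribution, clipped to [0,1].

    Plain sample mean/SD by default (the published range is computed on the
    full distribution, tails included); ``robust=True`` substitutes the
    median and a MAD-based SD for heavy-tailed archival cohorts.
    """
    ratios = np.asarray(ratios, float)
    if k <= 0:
        raise ValueError("k must be positive")
    if ratios.size < min_ratios:
        raise ValueError(
            f"need >= {min_ratios} ratios to estimate a normal range; "
            "use fixed conservative thresholds for small batches"
        )
    if robust:
        mean = float(np.median(ratios))
        sd = float(1.4826 * np.median(np.abs(ratios - mean)))
    else:
        mean = float(ratios.mean())
        sd = float(ratios.std(ddof=1))
    lower = max(0.0, mean - k * sd)
    upper = min(1.0, mean + k * sd)
    return ThresholdSet("sd_rule", mean, sd, k, lower, upper)


def conservative_thresholds(
    mean: float = 0.51,
    sd: float = 0.085,
    k: float = 3.0,
    *,
    as_band_max: float = AS_BAND_MAX,
    pws_band_min: float = PWS_BAND_MIN,
) -> ThresholdSet:
    """Fixed validation-panel bands (AS <= 0.12, PWS >= 0.88, inclusive)."""
    return ThresholdSet(
        "conservative",
        mean,
        sd,
        k,
        max(0.0, mean - k * sd),
        min(1.0, mean + k * sd),
        as_band_max,
        pws_band_min,
    )


def call_tier1(ratio: float, thresholds: ThresholdSet, sample_id: str = "") -> Tier1Call:
    """Band assignment: strict-outside under sd_rule, inclusive under conservative."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0,1]")
    if thresholds.mode == "sd_rule":
        if ratio < thresholds.lower:
            band = "low_band"
        elif ratio > thresholds.upper:
            band = "high_band"
        else:
            band = "negative"
    else:
        if ratio <= thresholds.as_band_max:
            band = "low_band"
        elif ratio >= thresholds.pws_band_min:
            band = "high_band"
        else:
            band = "negative"
    return Tier1Call(sample_id, float(ratio), band)


def screen_cohort(
    calls: Sequence,
    thresholds: ThresholdSet,
) -> tuple[list[Tier1Call], Tier1Summary]:
    """Apply tier-1 calling to a cohort of methylation calls.

    Accepts MethylationCall objects, (sample_id, ratio) pairs, or bare ratios.
    """
    if len(calls) == 0:
        raise ValueError("no calls supplied")
    tier1_calls = []
    for i, item in enumerate(calls):
        if hasattr(item, "ratio"):
            sid, ratio = item.sample_id, item.ratio
        elif isinstance(item, (tuple, list)):
            sid, ratio = item
        else:
            sid, ratio = f"S{i + 1:06d}", float(item)
        tier1_calls.append(call_tier1(ratio, thresholds, sid))
    n_low = sum(c.band == "low_band" for c in tier1_calls)
    n_high = sum(c.band == "high_band" for c in tier1_calls)
    return tier1_calls, Tier1Summary(len(tier1_calls), n_low, n_high)
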