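"""Second-tier methylation confirmation by two-channel droplet digital PCR.

Template molecules partition into droplets; a droplet is negative for a
channel when it received no copy of that template, which under Poisson
loading happens with probability exp(-lambda). Inverting,

    lambda = -ln(negatives / total)

gives mean copies per droplet for the methylated and unmethylated channels,
and the methylation ratio is lambda_meth / (lambda_meth + lambda_unmeth).
A sample is confirmed positive when its ratio falls strictly outside a
reference range built from storage-matched control wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DropletWell",
    "CinqCall",
    "SaturationError",
    "poisson_lambda",
    "simulate_droplets",
    "quantify_well",
    "reference_range",
    "call_cinq",
    "copies_per_microliter",
]

DROPLET_VOLUME_NL = 0.85  # assumed droplet volume for absolute-copies output


class SaturationError(ValueError):
    """All droplets positive: template concentration not quantifiable."""


@dataclass(frozen=True)
class DropletWell:
    sample_id: str
    total_droplets: int
    neg_meth: int
    neg_unmeth: int
    input_ng: float = 5.0  # 1-10 ng purified DNA (or DBS lysate equivalent)

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")
        for neg in (self.neg_meth, self.neg_unmeth):
            if not 0 <= neg <= self.total_droplets:
                raise ValueError("negative-droplet counts must be in [0, total]")


@dataclass(frozen=True)
class CinqCall:
    sample_id: str
    lambda_meth: float
    lambda_unmeth: float
    ratio: float
    confirmed: bool
    reference_range: tuple[float, float]
    qc_flags: tuple = ()


def poisson_lambda(neg: int, total: int) -> float:
    """Mean copies per droplet from the negative-droplet fraction."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= neg <= total:
        raise ValueError("neg must be in [0, total]")
    if neg == 0:
        raise SaturationError("all droplets positive; concentration unquantifiable")
    return -math.log(neg / total)


def simulate_droplets(
    methylation: float,
    copies_per_droplet: float = 1.0,
    total_droplets: int = 20_000,
    *,
    seed: int | None = None,
    sample_id: str = "",
    channel_bias: float = 1.0,
) -> DropletWell:
    """Forward model: channel loads m*lambda and (1-m)*lambda, Poisson partitioning.

    ``channel_bias`` multiplies the methylated-channel load to model unequal
    amplification efficiency between probes (1.0 = unbiased).
    """
    if not 0.0 <= methylation <= 1.0:
        raise ValueError("methylation must be in [0,1]")
    if copies_per_droplet <= 0 or total_droplets <= 0:
        raise ValueError("copies_per_droplet and total_droplets must be positive")
    rng = np.random.default_rng(seed)
    lam_meth = channel_bias * methylation * copies_per_droplet
    lam_unmeth = (1.0 - methylation) * copies_per_droplet
    neg_meth = int(rng.binomial(total_droplets, math.exp(-lam_meth)))
    neg_unmeth = int(rng.binomial(total_droplets, math.exp(-lam_unmeth)))
    return DropletWell(sample_id, total_droplets, neg_meth, neg_unmeth)


def quantify_well(well: DropletWell) -> tuple[float, float, float]:
    """(lambda_meth, lambda_unmeth, methylation ratio) for one well."""
    lam_m = poisson_lambda(well.neg_meth, well.total_droplets)
    lam_u = poisson_lambda(well.neg_unmeth, well.total_droplets)
    denom = lam_m + lam_u
    if denom <= 0:
        raise ValueError("no template detected on either channel")
    # Evaluate the smaller channel's fraction and complement the other, so
    # swapping channels maps ratio -> 1 - ratio exactly in floating point.
    if lam_m <= lam_u:
        ratio = lam_m / denom
    else:
        ratio = 1.0 - lam_u / denom
    return lam_m, lam_u, ratio


def reference_range(
    control_ratios: Sequence[float],
    *,
    min_controls: int = 20,
    method: str = "minmax",
    k: float = 4.0,
) -> tuple[float, float]:
    """Normal reference range from storage-matched control wells.

    Default is the published convention (min/max over >= 20 controls); a
    mean +/- k*SD alternative is available via ``method='sd'``.
    """
    ratios = np.asarray(control_ratios, float)
    if ratios.size < min_controls:
        raise ValueError(f"need >= {min_controls} control wells, got {ratios.size}")
    if method == "minmax":
        return float(ratios.min()), float(ratios.max())
    if method == "sd":
        return float(ratios.mean() - k * ratios.std(ddof=1)), float(
            ratios.mean() + k * ratios.std(ddof=1)
        )
    raise ValueError(f"unknown reference-range method {method!r}")


def call_cinq(
    well: DropletWell,
    ref_range: tuple[float, float],
) -> CinqCall:
    """Confirmed positive iff the methylation ratio is strictly outside the range.

    Channel saturation propagates as a qc failure (never a confirmed call).
    """
    low, high = ref_range
    if low > high:
        raise ValueError("reference range is inverted")
    try:
        lam_m, lam_u, ratio = quantify_well(well)
    except SaturationError:
        return CinqCall(
            well.sample_id,
            math.nan,
            math.nan,
            math.nan,
            confirmed=False,
            reference_range=(low, high),
            qc_flags=("saturation",),
        )
    confirmed = ratio < low or ratio > high
    return CinqCall(well.sample_id, lam_m, lam_u, ratio, confirmed, (low, high))


def copies_per_microliter(lam: float, droplet_volume_nl: float = DROPLET_VOLUME_NL) -> float:
    """Convenience absolute concentration given an assumed droplet volume."""
    return lam / (droplet_volume_nl * 1e-3)
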