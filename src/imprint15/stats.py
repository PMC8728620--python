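"""Screening performance statistics: PPV, prevalence, exact binomial CIs, tier flow.

Conventions follow newborn-screening reporting practice: PPV is confirmed
positives over screen positives; prevalence is confirmed positives over all
screened, rendered as "1 in N"; intervals are exact Clopper-Pearson from
inverting binomial tails; percents are rendered half-away-from-zero to one
decimal (two decimals for sub-1% rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import beta as beta_dist

from ._util import one_in_n_str, percent_str, round_half_away

__all__ = [
    "ConfusionTable",
    "Prevalence",
    "ppv",
    "npv",
    "prevalence",
    "sensitivity_specificity",
    "clopper_pearson",
    "TierFlow",
    "tier_flow",
]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int
    stratum: str = "combined"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def ppv(confirmed: int, flagged: int) -> float:
    """Confirmed positives / screen positives."""
    if flagged <= 0:
        raise ValueError("flagged must be positive")
    if not 0 <= confirmed <= flagged:
        raise ValueError("need 0 <= confirmed <= flagged")
    return confirmed / flagged


def npv(true_negative: int, screen_negative: int) -> float:
    if screen_negative <= 0:
        raise ValueError("screen_negative must be positive")
    return true_negative / screen_negative


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI by beta-quantile inversion of the binomial tails."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0,1)")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


@dataclass(frozen=True)
class Prevalence:
    confirmed: int
    screened: int
    fraction: float
    one_in_n: int | None
    ci_low: float
    ci_high: float

    @property
    def text(self) -> str:
        """'1 in N' rendering (spaces group thousands for 5+ digit N)."""
        if self.one_in_n is None:
            return "0 confirmed"
        return one_in_n_str(self.one_in_n)


def prevalence(confirmed: int, screened: int, level: float = 0.95) -> Prevalence:
    """Prevalence with exact 95% CI; one_in_n rounds half away from zero."""
    if screened <= 0:
        raise ValueError("screened must be positive")
    if not 0 <= confirmed <= screened:
        raise ValueError("need 0 <= confirmed <= screened")
    fraction = confirmed / screened
    one_in_n = int(round_half_away(screened / confirmed)) if confirmed > 0 else None
    low, high = clopper_pearson(confirmed, screened, level)
    return Prevalence(confirmed, screened, fraction, one_in_n, low, high)


def sensitivity_specificity(table: ConfusionTable) -> tuple[float, float]:
    if table.tp + table.fn <= 0:
        raise ValueError("sensitivity undefined: no condition-positive samples")
    if table.tn + table.fp <= 0:
        raise ValueError("specificity undefined: no condition-negative samples")
    return table.tp / (table.tp + table.fn), table.tn / (table.tn + table.fp)


@dataclass(frozen=True)
class TierFlow:
    """Tier-flow accounting with the conservation identities built in."""

    n_screened: int
    n_flagged_t1: int
    n_confirmed_t2: int
    n_unconfirmed_t2: int
    n_qc_failed_t2: int
    per_condition: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_flagged_t1 != self.n_confirmed_t2 + self.n_unconfirmed_t2 + self.n_qc_failed_t2:
            raise ValueError("tier-2 outcomes do not conserve the flagged count")
        if not 0 <= self.n_flagged_t1 <= self.n_screened:
            raise ValueError("flagged count exceeds screened count")

    @property
    def n_negative_t1(self) -> int:
        return self.n_screened - self.n_flagged_t1

    @property
    def overall_ppv(self) -> float | None:
        return ppv(self.n_confirmed_t2, self.n_flagged_t1) if self.n_flagged_t1 else None


_CONDITION_OF_CLASS = {
    "PWS_deletion": "PWS",
    "PWS_UPD_or_ID": "PWS",
    "PWS_mosaic": "PWS",
    "AS_deletion": "AS",
    "AS_nondeletion": "AS",
    "AS_UBE3A_mutation": "AS",
    "Dup15q_interstitial_maternal": "Dup15q",
    "Dup15q_idic15": "Dup15q",
    "Dup15q_tricentric": "Dup15q",
}


def condition_of(genotype: str) -> str:
    """Collapse genotype classes to the screened condition (or 'control')."""
    return _CONDITION_OF_CLASS.get(genotype, "control")


def tier_flow(
    truth: Mapping[str, str],
    flagged_ids: Sequence[str],
    confirmed_ids: Sequence[str],
    qc_failed_ids: Sequence[str] = (),
    *,
    band_of: Mapping[str, str] | None = None,
) -> TierFlow:
    """Assemble the screened -> flagged -> confirmed accounting.

    ``truth`` maps every screened sample id to its genotype class. Flagged,
    confirmed and qc-failed ids must be subsets of the screened ids, with
    confirmed and qc-failed subsets of flagged. Per-condition PPV, prevalence
    and CIs are computed over confirmed cases grouped by condition; when
    ``band_of`` (sample id -> tier-1 band) is given, each condition's PPV
    denominator is the flagged count in its own band (low band for AS, high
    band for PWS and Dup15q), otherwise all flagged samples.
    """
    screened = set(truth)
    flagged = set(flagged_ids)
    confirmed = set(confirmed_ids)
    qc_failed = set(qc_failed_ids)
    if not flagged <= screened:
        raise ValueError("flagged ids not among screened ids")
    if not (confirmed <= flagged and qc_failed <= flagged):
        raise ValueError("tier-2 ids not among flagged ids")
    if confirmed & qc_failed:
        raise ValueError("a sample cannot be both confirmed and qc-failed")

    n = len(screened)
    band_for_condition = {"AS": "low_band", "PWS": "high_band", "Dup15q": "high_band"}
    per_condition: dict[str, dict[str, float]] = {}
    conditions = sorted({condition_of(g) for g in truth.values()} - {"control"})
    for cond in conditions + ["combined"]:
        if cond == "combined":
            conf = len(confirmed)
            flag = len(flagged)
        else:
            conf = sum(1 for s in confirmed if condition_of(truth[s]) == cond)
            if band_of is not None:
                band = band_for_condition.get(cond)
                flag = sum(1 for s in flagged if band_of.get(s) == band)
            else:
                flag = len(flagged)
        prev = prevalence(conf, n)
        entry: dict[str, float] = {
            "confirmed": conf,
            "flagged": flag,
            "prevalence_fraction": prev.fraction,
            "ci_low": prev.ci_low,
            "ci_high": prev.ci_high,
        }
        if prev.one_in_n is not None:
            entry["one_in_n"] = prev.one_in_n
            entry["prevalence_text"] = prev.text
        if flag > 0:
            entry["ppv"] = ppv(conf, flag)
            entry["ppv_percent"] = percent_str(entry["ppv"])
        per_condition[cond] = entry

    return TierFlow(
        n_screened=n,
        n_flagged_t1=len(flagged),
        n_confirmed_t2=len(confirmed),
        n_unconfirmed_t2=len(flagged) - len(confirmed) - len(qc_failed),
        n_qc_failed_t2=len(qc_failed),
        per_condition=per_condition,
    )
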