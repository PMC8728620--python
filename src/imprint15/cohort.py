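"""Synthetic newborn cohorts for chromosome 15 imprinting-disorder screening.

The simulator encodes the parent-of-origin model of the SNRPN promoter:
the maternal copy is methylated, the paternal copy unmethylated, so the
true methylation fraction of a genotype is

    true_meth = (methylated maternal copies) / (total copies)

Controls carry one copy of each (0.5); Prader-Willi syndrome (PWS) lacks
the paternal copy (1.0); Angelman syndrome (AS) lacks the maternal copy
(0.0); a maternal interstitial duplication has 2 of 3 copies methylated
(2/3); an isodicentric chromosome 15 (idic15) has 3 of 4 (3/4); a
tricentric supernumerary has 5 of 7 (5/7). AS caused by a UBE3A point
mutation keeps normal methylation (0.5) and is the screen's known blind
spot.

Copy-number profiles are expressed on NC_000015.9 (GRCh37) coordinates
over the modeled window chr15:20,000,000-35,000,000, using the recurrent
breakpoints BP1-BP5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeClass",
    "CohortSample",
    "AssayNoise",
    "GENOTYPE_CLASSES",
    "DUPLICATION_CLASSES",
    "class_mix",
    "true_methylation",
    "effective_methylation",
    "make_cohort",
    "draw_melt_methylation",
    "ddpcr_methylation",
    "emit_sample_sheet",
    "read_sample_sheet",
    "masked_sample_sheet",
]

# Modeled chromosome 15 window (bp, 0-based half-open) and breakpoint anchors.
REGION_START = 20_000_000
REGION_END = 35_000_000

# (start, end, copy_number) spans; anything not covered is 2 copies.
_CN2: tuple = ()
_DEL_BP2_BP3 = ((23_100_000, 28_300_000, 1),)
_DUP_BP2_BP3 = ((23_100_000, 28_300_000, 3),)
_IDIC15 = ((22_550_000, 30_100_000, 4), (30_300_000, 32_250_000, 3))
_TRICENTRIC = ((22_550_000, 30_100_000, 7),)


@dataclass(frozen=True)
class GenotypeClass:
    """A latent genotype with its parent-of-origin methylation and CN profile."""

    name: str
    true_meth: float
    cn_profile: tuple = _CN2  # (start, end, copies) spans; gaps are CN=2
    mosaic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_meth <= 1.0:
            raise ValueError(f"true_meth must be in [0,1], got {self.true_meth}")
        for start, end, cn in self.cn_profile:
            if cn < 0 or int(cn) != cn:
                raise ValueError(f"copy numbers must be integers >= 0, got {cn}")
            if not (REGION_START <= start < end <= REGION_END):
                raise ValueError(f"span ({start},{end}) outside modeled region")


GENOTYPE_CLASSES: dict[str, GenotypeClass] = {
    g.name: g
    for g in [
        GenotypeClass("control", 0.5),
        GenotypeClass("PWS_deletion", 1.0, _DEL_BP2_BP3),
        GenotypeClass("PWS_UPD_or_ID", 1.0),
        GenotypeClass("PWS_mosaic", 1.0, mosaic=True),
        GenotypeClass("AS_deletion", 0.0, _DEL_BP2_BP3),
        GenotypeClass("AS_nondeletion", 0.0),
        GenotypeClass("AS_UBE3A_mutation", 0.5),
        GenotypeClass("Dup15q_interstitial_maternal", 2.0 / 3.0, _DUP_BP2_BP3),
        GenotypeClass("Dup15q_idic15", 3.0 / 4.0, _IDIC15),
        GenotypeClass("Dup15q_tricentric", 5.0 / 7.0, _TRICENTRIC),
    ]
}

DUPLICATION_CLASSES = frozenset(
    {"Dup15q_interstitial_maternal", "Dup15q_idic15", "Dup15q_tricentric"}
)


def class_mix(**counts_or_fracs: float) -> dict[str, float]:
    """Build a prevalence table; unnamed remainder goes to controls.

    Values are fractions; 'control' is filled with 1 - sum(others) when absent.
    """
    mix = dict(counts_or_fracs)
    unknown = set(mix) - set(GENOTYPE_CLASSES)
    if unknown:
        raise ValueError(f"unknown genotype classes: {sorted(unknown)}")
    if "control" not in mix:
        mix["control"] = 1.0 - sum(mix.values())
    total = sum(mix.values())
    if any(p < 0 or p > 1 for p in mix.values()) or abs(total - 1.0) > 1e-9:
        raise ValueError(f"prevalences must be in [0,1] and sum to 1, got sum {total}")
    return mix


def true_methylation(genotype: GenotypeClass | str, mosaic_fraction: float = 1.0) -> float:
    """Effective methylation under the parent-of-origin model.

    A mosaic carries the abnormal genotype in `mosaic_fraction` of cells and
    the 0.5 baseline elsewhere.
    """
    if isinstance(genotype, str):
        genotype = GENOTYPE_CLASSES[genotype]
    if not 0.0 <= mosaic_fraction <= 1.0:
        raise ValueError("mosaic_fraction must be in [0,1]")
    return mosaic_fraction * genotype.true_meth + (1.0 - mosaic_fraction) * 0.5


effective_methylation = true_methylation


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    genotype: str
    mosaic_fraction: float = 1.0
    tissue: str = "NBS"
    storage_years: float = 5.0
    plate_id: str = "P0001"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_CLASSES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if not GENOTYPE_CLASSES[self.genotype].mosaic and self.mosaic_fraction != 1.0:
            raise ValueError("mosaic_fraction must be 1 for non-mosaic classes")
        if self.storage_years < 0:
            raise ValueError("storage_years must be nonnegative")

    @property
    def true_meth(self) -> float:
        return true_methylation(self.genotype, self.mosaic_fraction)


@dataclass(frozen=True)
class AssayNoise:
    """Dispersion model for the first-tier melt measurement.

    Controls: truncated Normal(control_mean, control_sd) — 0.51 and 0.085,
    so that mean ± 3 SD spans 0.255, plus a Student-t artifact mixture whose
    weight and tail heaviness grow with archival storage (long-stored blood
    spots show broader distribution tails). Affected classes are modeled as
    tight clusters around their class methylation (affected_sd), with
    duplication genotypes reading high on the melt assay by dup_melt_bias;
    this places an idic15 (true 0.75) near 0.80, inside the band that the
    ±3SD rule flags but the conservative 0.88 cutoff does not.
    """

    control_mean: float = 0.51
    control_sd: float = 0.085
    affected_sd: float = 0.008
    dup_melt_bias: float = 0.05
    tail_weight_max: float = 0.052
    tail_scale: float = 0.12
    tail_years_const: float = 2.5
    affected_tails: bool = False

    def tail_weight(self, storage_years: np.ndarray) -> np.ndarray:
        return self.tail_weight_max * (1.0 - np.exp(-np.asarray(storage_years, float) / self.tail_years_const))

    def tail_df(self, storage_years: np.ndarray) -> np.ndarray:
        return np.maximum(3.0, 30.0 / (1.0 + np.asarray(storage_years, float)))


def make_cohort(
    n: int,
    mix: Mapping[str, float] | None = None,
    *,
    seed: int,
    exact_counts: bool = False,
    storage_years: float = 5.0,
    tissue: str = "NBS",
    samples_per_plate: int = 94,
    mosaic_fraction_range: tuple[float, float] = (0.2, 0.8),
) -> list[CohortSample]:
    """Generate n newborn samples with genotype classes drawn from `mix`.

    Classes are multinomially assigned by default; with ``exact_counts=True``
    each class receives round(n * prevalence) samples (largest-remainder
    correction keeps the total at n), which is how rare confirmed cases are
    pinned to exact counts. Affected samples are shuffled into the cohort
    reproducibly under `seed`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = class_mix(**(dict(mix) if mix is not None else {}))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x15C0]))
    names = sorted(mix)
    probs = np.array([mix[name] for name in names])

    if exact_counts:
        raw = probs * n
        counts = np.floor(raw).astype(int)
        remainder = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:remainder]] += 1
    else:
        counts = rng.multinomial(n, probs)

    labels = np.repeat(names, counts)
    rng.shuffle(labels)

    lo, hi = mosaic_fraction_range
    samples = []
    for i, name in enumerate(labels):
        gclass = GENOTYPE_CLASSES[name]
        # Rounded so sample sheets round-trip exactly through TSV.
        frac = round(float(rng.uniform(lo, hi)), 6) if gclass.mosaic else 1.0
        samples.append(
            CohortSample(
                sample_id=f"S{i + 1:06d}",
                genotype=name,
                mosaic_fraction=frac,
                tissue=tissue,
                storage_years=storage_years,
                plate_id=f"P{i // samples_per_plate + 1:04d}",
            )
        )
    return samples


def _as_arrays(cohort: Sequence[CohortSample]):
    meth = np.array([s.true_meth for s in cohort])
    storage = np.array([s.storage_years for s in cohort])
    is_control = np.array([s.genotype == "control" for s in cohort])
    is_dup = np.array([s.genotype in DUPLICATION_CLASSES for s in cohort])
    return meth, storage, is_control, is_dup


def draw_melt_methylation(
    cohort: Sequence[CohortSample],
    noise: AssayNoise | None = None,
    *,
    seed: int,
) -> np.ndarray:
    """Per-sample methylation fraction as the melt assay will encode it.

    This is the biological truth passed through sample-level assay
    dispersion (storage artifacts, within-class spread, duplication melt
    bias); the melt forward model then adds only curve-level noise.
    """
    noise = noise or AssayNoise()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3E17]))
    meth, storage, is_control, is_dup = _as_arrays(cohort)
    n = len(cohort)

    out = np.empty(n)
    # Controls: truncated normal core.
    z = rng.standard_normal(n)
    core = noise.control_mean + noise.control_sd * z
    # Resample the (rare) out-of-range control draws rather than clipping,
    # to avoid point masses at 0/1.
    bad = is_control & ((core < 0) | (core > 1))
    while bad.any():
        core[bad] = noise.control_mean + noise.control_sd * rng.standard_normal(bad.sum())
        bad = is_control & ((core < 0) | (core > 1))
    out[is_control] = core[is_control]

    # Affected classes: tight cluster at class methylation (+ melt bias for dups).
    center = meth + np.where(is_dup, noise.dup_melt_bias, 0.0)
    aff = ~is_control
    out[aff] = center[aff] + noise.affected_sd * rng.standard_normal(n)[aff]

    # Storage-driven artifact tails (heavy-tailed melt artifacts in degraded DNA).
    w = noise.tail_weight(storage)
    df = noise.tail_df(storage)
    take_tail = rng.uniform(size=n) < w
    if not noise.affected_tails:
        take_tail &= is_control
    if take_tail.any():
        t_draws = rng.standard_t(df[take_tail])
        out[take_tail] = noise.control_mean + noise.tail_scale * t_draws

    return np.clip(out, 0.0, 1.0)


def ddpcr_methylation(
    cohort: Sequence[CohortSample],
    *,
    seed: int,
    biological_sd: float = 0.003,
) -> np.ndarray:
    """True methylation with small between-sample biological spread.

    The droplet assay reads bisulfite-converted template directly, so melt
    artifacts and duplication melt bias do not carry over to this tier.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDD9C]))
    meth = np.array([s.true_meth for s in cohort])
    return np.clip(meth + biological_sd * rng.standard_normal(len(cohort)), 0.0, 1.0)


_TRUTH_COLUMNS = ["truth_genotype", "truth_mosaic_fraction", "truth_methylation"]


def cohort_frame(cohort: Sequence[CohortSample]) -> pd.DataFrame:
    """Sample sheet as a DataFrame; latent truth columns carry a truth_ prefix."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort],
            "plate_id": [s.plate_id for s in cohort],
            "tissue": [s.tissue for s in cohort],
            "storage_years": [s.storage_years for s in cohort],
            "truth_genotype": [s.genotype for s in cohort],
            "truth_mosaic_fraction": [s.mosaic_fraction for s in cohort],
            "truth_methylation": [s.true_meth for s in cohort],
        }
    )


def emit_sample_sheet(cohort: Sequence[CohortSample], path: str | Path) -> Path:
    """Write the cohort as a TSV sample sheet (header + one row per sample)."""
    if not cohort:
        raise ValueError("cohort is empty")
    path = Path(path)
    cohort_frame(cohort).to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path: str | Path) -> list[CohortSample]:
    df = pd.read_csv(path, sep="\t")
    return [
        CohortSample(
            sample_id=str(row.sample_id),
            genotype=str(row.truth_genotype),
            mosaic_fraction=float(row.truth_mosaic_fraction),
            tissue=str(row.tissue),
            storage_years=float(row.storage_years),
            plate_id=str(row.plate_id),
        )
        for row in df.itertuples()
    ]


def masked_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Caller-facing view of a sample sheet with all truth_ columns removed."""
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=[c for c in df.columns if c.startswith("truth_")])
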