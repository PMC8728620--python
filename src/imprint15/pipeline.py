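"""End-to-end orchestration: generate -> tier 1 -> tier 2 -> tier 3 -> report.

``run`` drives the whole simulated screening workflow from a RunConfig and
writes standard-format artifacts (TSV sample sheet and call tables, BED plus
an HGVS sidecar for LC-WGS segments, a JSON report, a structured log). Every
stochastic stage receives its own sub-seed derived from the master seed, so
a config reproduces its report byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import cnv as cnv_mod
from . import ddpcr as ddpcr_mod
from . import lcwgs as lcwgs_mod
from . import melt as melt_mod
from . import stats as stats_mod
from . import tier1 as tier1_mod

__all__ = ["ConfigError", "RunConfig", "run"]

PACKAGE_VERSION = "0.1.0"


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


@dataclass(frozen=True)
class RunConfig:
    n: int = 16_579
    class_mix: Mapping[str, float] = field(default_factory=dict)
    exact_counts: bool = False
    storage_years: float = 5.0
    threshold_mode: str = "sd"  # sd | conservative
    k: float = 3.0
    seed: int = 0
    # first tier
    melt_noise_sd: float = 0.003
    plate_shift_sd: float = 0.005
    assay_noise: Mapping[str, float] = field(default_factory=dict)
    # second tier
    copies_per_droplet: float = 1.0
    total_droplets: int = 20_000
    n_reference_controls: int = 20
    reference_panel_sd: float = 0.02
    ddpcr_biological_sd: float = 0.003
    # third tier
    coverage_per_bin: float = 100.0
    min_bins: int = 4

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.threshold_mode not in ("sd", "conservative"):
            raise ConfigError("threshold_mode must be 'sd' or 'conservative'")
        if self.k <= 0:
            raise ConfigError("k must be positive")
        try:
            cohort_mod.class_mix(**dict(self.class_mix))
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        unknown = set(self.assay_noise) - {
            f.name for f in dataclasses.fields(cohort_mod.AssayNoise)
        }
        if unknown:
            raise ConfigError(f"unknown assay_noise keys: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["class_mix"] = dict(self.class_mix)
        out["assay_noise"] = dict(self.assay_noise)
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sub_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % 2**31 for s in ss.generate_state(n)]


def _imprinted_copies(genotype: str) -> int:
    profile = cohort_mod.GENOTYPE_CLASSES[genotype].cn_profile
    for start, end, copies in profile:
        if start <= lcwgs_mod.IMPRINTED_CENTER < end:
            return copies
    return 2


def _tier2(cohort, flagged, band_by_id, config: RunConfig, seeds) -> pd.DataFrame:
    """ddPCR methylation confirmation plus CNV qPCR for the flagged samples."""
    rng_ref, rng_well, rng_cnv = (np.random.default_rng(s) for s in seeds)

    # Reference range from storage-matched control wells chosen to span the
    # cohort's storage/quality extremes (wider spread than a random control).
    ref_truth = np.clip(
        0.5 + config.reference_panel_sd * rng_ref.standard_normal(config.n_reference_controls),
        0.0,
        1.0,
    )
    ref_ratios = []
    for m in ref_truth:
        well = ddpcr_mod.simulate_droplets(
            float(m),
            config.copies_per_droplet,
            config.total_droplets,
            seed=int(rng_ref.integers(2**31)),
        )
        ref_ratios.append(ddpcr_mod.quantify_well(well)[2])
    ref_range = ddpcr_mod.reference_range(
        ref_ratios, min_controls=min(20, config.n_reference_controls)
    )

    by_id = {s.sample_id: s for s in cohort}
    flagged_samples = [by_id[sid] for sid in flagged]
    ddpcr_truth = cohort_mod.ddpcr_methylation(
        flagged_samples,
        seed=int(rng_well.integers(2**31)),
        biological_sd=config.ddpcr_biological_sd,
    )

    curve_t = cnv_mod.ideal_standard_curve(intercept=26.0)
    curve_r = cnv_mod.ideal_standard_curve(intercept=24.0)
    ranges = cnv_mod.default_reference_ranges()

    rows = []
    for sample, m_true in zip(flagged_samples, ddpcr_truth):
        well = ddpcr_mod.simulate_droplets(
            float(m_true),
            config.copies_per_droplet,
            config.total_droplets,
            seed=int(rng_well.integers(2**31)),
            sample_id=sample.sample_id,
        )
        cinq = ddpcr_mod.call_cinq(well, ref_range)

        copies = _imprinted_copies(sample.genotype)
        ct_t, ct_r = cnv_mod.simulate_sample_cts(
            copies, curve_t, curve_r, seed=int(rng_cnv.integers(2**31))
        )
        ratio = float(cnv_mod.cnv_ratio(ct_t, ct_r, curve_t, curve_r))
        cnv_call = cnv_mod.classify_cnv(ratio, ranges, sample_id=sample.sample_id)

        rows.append(
            {
                "sample_id": sample.sample_id,
                "tier1_band": band_by_id[sample.sample_id],
                "cinq_ratio": cinq.ratio,
                "cinq_confirmed": cinq.confirmed,
                "cinq_qc": ";".join(cinq.qc_flags),
                "cnv_ratio": cnv_call.cnv_ratio,
                "cnv_class": -1 if cnv_call.copy_class is None else cnv_call.copy_class,
                "cnv_reflex": cnv_call.reflex_lcwgs,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "tier1_band",
            "cinq_ratio",
            "cinq_confirmed",
            "cinq_qc",
            "cnv_ratio",
            "cnv_class",
            "cnv_reflex",
        ],
    )
    df.attrs["reference_range"] = ref_range
    return df


def _tier3(cohort, reflex_ids, band_by_id, config: RunConfig, seed: int):
    rng = np.random.default_rng(seed)
    by_id = {s.sample_id: s for s in cohort}
    results = {}
    for sid in sorted(reflex_ids):
        sample = by_id[sid]
        profile = cohort_mod.GENOTYPE_CLASSES[sample.genotype].cn_profile
        track = lcwgs_mod.simulate_bins(
            profile, config.coverage_per_bin, seed=int(rng.integers(2**31))
        )
        segments = lcwgs_mod.segment_and_call(track, min_bins=config.min_bins)
        band = {"low_band": "low", "high_band": "high"}.get(band_by_id.get(sid, ""), None)
        subtype = lcwgs_mod.assign_breakpoints(segments, methylation_band=band)
        results[sid] = (segments, subtype)
    return results


def run(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full screening workflow; returns (and optionally writes) the report."""
    seeds = _sub_seeds(config.seed)
    log_lines: list[str] = []

    def log(stage: str, **counts) -> None:
        log_lines.append(json.dumps({"stage": stage, **counts}, sort_keys=True))

    # Generate
    cohort = cohort_mod.make_cohort(
        config.n,
        dict(config.class_mix),
        seed=seeds[0],
        exact_counts=config.exact_counts,
        storage_years=config.storage_years,
    )
    log("generate", n=len(cohort))

    # Tier 1: melt, quantify, calibrate, threshold
    noise = cohort_mod.AssayNoise(**dict(config.assay_noise))
    m_assay = cohort_mod.draw_melt_methylation(cohort, noise, seed=seeds[1])
    calibration = melt_mod.fit_calibration(melt_mod.make_standards())
    ratios = melt_mod.measure_cohort(
        m_assay,
        [s.plate_id for s in cohort],
        calibration,
        seed=seeds[2],
        noise_sd=config.melt_noise_sd,
        plate_shift_sd=config.plate_shift_sd,
    )
    try:
        sd_thresholds = tier1_mod.compute_thresholds(ratios, config.k)
    except ValueError:
        # Too few samples to estimate a normal range: fall back to the
        # published population values (mean 0.51, SD 0.085).
        sd_thresholds = tier1_mod.ThresholdSet(
            "sd_rule",
            0.51,
            0.085,
            config.k,
            max(0.0, 0.51 - config.k * 0.085),
            min(1.0, 0.51 + config.k * 0.085),
        )
    cons_thresholds = tier1_mod.conservative_thresholds(
        sd_thresholds.mean, sd_thresholds.sd, config.k
    )
    ids = [s.sample_id for s in cohort]
    calls_sd, summary_sd = tier1_mod.screen_cohort(list(zip(ids, ratios)), sd_thresholds)
    calls_cons, summary_cons = tier1_mod.screen_cohort(list(zip(ids, ratios)), cons_thresholds)
    primary_calls, primary_summary, primary_thresholds = (
        (calls_sd, summary_sd, sd_thresholds)
        if config.threshold_mode == "sd"
        else (calls_cons, summary_cons, cons_thresholds)
    )
    log(
        "tier1",
        n_in=len(cohort),
        n_flagged_sd=summary_sd.n_referred,
        n_flagged_conservative=summary_cons.n_referred,
    )

    # Tier 2 on the union of both modes' flags (conservative is nested in sd).
    band_by_id = {c.sample_id: c.band for c in calls_sd}
    band_by_id.update({c.sample_id: c.band for c in calls_cons if c.referred})
    flagged_primary = [c.sample_id for c in primary_calls if c.referred]
    flagged_union = sorted(
        {c.sample_id for c in calls_sd if c.referred}
        | {c.sample_id for c in calls_cons if c.referred}
    )
    tier2 = _tier2(cohort, flagged_union, band_by_id, config, seeds[3:6])
    tier2_by_id = tier2.set_index("sample_id")
    confirmed_primary = [
        sid for sid in flagged_primary if bool(tier2_by_id.loc[sid, "cinq_confirmed"])
    ]
    qc_failed = [
        sid
        for sid in flagged_primary
        if "saturation" in str(tier2_by_id.loc[sid, "cinq_qc"])
    ]
    log("tier2", n_in=len(flagged_union), n_confirmed=len(confirmed_primary))

    # Tier 3: methylation-confirmed samples with a non-diploid (or extreme) CNV result.
    reflex_ids = [
        sid
        for sid in confirmed_primary
        if int(tier2_by_id.loc[sid, "cnv_class"]) != 2
        or bool(tier2_by_id.loc[sid, "cnv_reflex"])
    ]
    tier3 = _tier3(cohort, reflex_ids, band_by_id, config, seeds[6])
    log("tier3", n_in=len(reflex_ids), n_typed=len(tier3))

    # Report
    truth = {s.sample_id: s.genotype for s in cohort}
    flows = {}
    for mode, calls in (("sd", calls_sd), ("conservative", calls_cons)):
        flg = [c.sample_id for c in calls if c.referred]
        conf = [s for s in flg if bool(tier2_by_id.loc[s, "cinq_confirmed"])]
        qcf = [s for s in flg if "saturation" in str(tier2_by_id.loc[s, "cinq_qc"])]
        flow = stats_mod.tier_flow(
            truth, flg, conf, qcf, band_of={c.sample_id: c.band for c in calls}
        )
        flows[mode] = {
            "n_screened": flow.n_screened,
            "n_flagged": flow.n_flagged_t1,
            "n_confirmed": flow.n_confirmed_t2,
            "n_unconfirmed": flow.n_unconfirmed_t2,
            "n_qc_failed": flow.n_qc_failed_t2,
            "per_condition": {k: dict(v) for k, v in flow.per_condition.items()},
        }

    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": PACKAGE_VERSION,
            "threshold_mode": config.threshold_mode,
        },
        "thresholds": {
            "sd_rule": {
                "mean": round(sd_thresholds.mean, 6),
                "sd": round(sd_thresholds.sd, 6),
                "lower": round(sd_thresholds.lower, 6),
                "upper": round(sd_thresholds.upper, 6),
            },
            "conservative": {
                "as_band_max": cons_thresholds.as_band_max,
                "pws_band_min": cons_thresholds.pws_band_min,
            },
        },
        "tier1": {
            "n_screened": primary_summary.n_screened,
            "n_low": primary_summary.n_low,
            "n_high": primary_summary.n_high,
            "n_referred": primary_summary.n_referred,
            "percent_referred": primary_summary.percent_referred,
        },
        "tier2": {
            "reference_range": [round(x, 6) for x in tier2.attrs["reference_range"]],
            "n_confirmed": len(confirmed_primary),
            "confirmed_ids": sorted(confirmed_primary),
        },
        "tier3": {
            sid: {
                "subtype": subtype.label,
                "breakpoints": list(subtype.breakpoints),
                "segments": [
                    {"hgvs": seg.full_hgvs, "copy_number": seg.copy_number}
                    for seg in segments
                ],
            }
            for sid, (segments, subtype) in tier3.items()
        },
        "flows": flows,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort_mod.emit_sample_sheet(cohort, outdir / "sample_sheet.tsv")
        pd.DataFrame(
            {
                "sample_id": ids,
                "ratio": np.round(ratios, 6),
                "band": [c.band for c in primary_calls],
                "referred": [c.referred for c in primary_calls],
            }
        ).to_csv(outdir / "tier1_calls.tsv", sep="\t", index=False)
        tier2.to_csv(outdir / "tier2_calls.tsv", sep="\t", index=False)
        bed_rows = []
        hgvs_rows = []
        for sid, (segments, subtype) in tier3.items():
            for seg in segments:
                bed_rows.append(
                    f"chr15\t{seg.start}\t{seg.end}\t{sid};CN={seg.copy_number}"
                )
                hgvs_rows.append(
                    {
                        "sample_id": sid,
                        "hgvs": seg.full_hgvs,
                        "copy_number": seg.copy_number,
                        "subtype": subtype.label,
                    }
                )
        (outdir / "lcwgs_segments.bed").write_text(
            "\n".join(bed_rows) + ("\n" if bed_rows else "")
        )
        pd.DataFrame(
            hgvs_rows, columns=["sample_id", "hgvs", "copy_number", "subtype"]
        ).to_csv(outdir / "lcwgs_segments.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return report
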