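"""Third-tier copy-number typing from low-coverage WGS read-depth bins.

Reads are counted in fixed-width bins (default 50 kb) over the modeled
chr15q11-q13 window; each bin's depth relative to a diploid baseline is a
log2 ratio (0 at 2 copies, -1 at 1 copy, 0.585 at 3, 1 at 4). Bins are
median-smoothed, classified to the nearest copy band, merged into segments,
and segment boundaries are snapped to the recurrent breakpoints BP1-BP5 to
type the event: BP1-BP3 deletions are "type I", BP2-BP3 "type II" (AS vs PWS
disambiguated by the first-tier methylation band), CN=4 over the imprinted
center is an isodicentric 15 (idic15), CN=3 alone an interstitial
duplication.

Internal coordinates are 0-based half-open; HGVS g. descriptions are 1-based
inclusive (NC_000015.9 / GRCh37).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "CONTIG",
    "REGION",
    "BIN_SIZE",
    "BP_MAP",
    "IMPRINTED_CENTER",
    "CnSegment",
    "SubtypeCall",
    "simulate_bins",
    "segment_and_call",
    "assign_breakpoints",
    "segments_to_track",
    "to_hgvs",
    "parse_hgvs",
]

CONTIG = "NC_000015.9"
REGION = (20_000_000, 35_000_000)
BIN_SIZE = 50_000
IMPRINTED_CENTER = 25_200_000  # SNRPN locus, 15q11.2

# Approximate recurrent breakpoint anchors (GRCh37), config-overridable.
BP_MAP: dict[str, int] = {
    "BP1": 22_300_000,
    "BP2": 23_100_000,
    "BP3": 28_300_000,
    "BP4": 30_300_000,
    "BP5": 32_250_000,
}


def to_hgvs(start: int, end: int, copy_number: int) -> str:
    """0-based half-open span -> 1-based inclusive g. description."""
    if copy_number < 2:
        return f"g.{start + 1}_{end}del"
    return f"g.{start + 1}_{end}[{copy_number}]"


_HGVS_RE = re.compile(r"g\.(\d+)_(\d+)(?:del|\[(\d+)\])$")


def parse_hgvs(hgvs: str) -> tuple[int, int, int]:
    """Inverse of :func:`to_hgvs`; deletions parse as copy number 1."""
    m = _HGVS_RE.search(hgvs)
    if not m:
        raise ValueError(f"cannot parse HGVS description {hgvs!r}")
    start1, end1, copies = m.groups()
    return int(start1) - 1, int(end1), int(copies) if copies else 1


@dataclass(frozen=True)
class CnSegment:
    start: int  # bp, 0-based half-open
    end: int
    copy_number: int

    @property
    def hgvs(self) -> str:
        return to_hgvs(self.start, self.end, self.copy_number)

    @property
    def full_hgvs(self) -> str:
        return f"{CONTIG}:{self.hgvs}"


@dataclass(frozen=True)
class SubtypeCall:
    label: str  # AS/PWS_del_typeI/II, interstitial_dup, idic15, tricentric, normal, unclassified
    breakpoints: tuple[str, ...]
    center_copy_number: int
    unsnapped: tuple[int, ...] = ()  # boundaries with no BP within the window


def simulate_bins(
    cn_profile: Sequence[tuple[int, int, int]],
    mean_coverage_per_bin: float = 100.0,
    *,
    seed: int | None = None,
    bin_size: int = BIN_SIZE,
    region: tuple[int, int] = REGION,
    n_baseline_bins: int = 2000,
) -> pd.DataFrame:
    """Poisson read counts per bin for a copy-number profile; gaps are 2 copies.

    Counts are normalized to the median of co-simulated diploid baseline bins
    (2000 by default, standing in for autosomal-normal coverage elsewhere in
    the genome) — a sample whose chr15 window is mostly duplicated must not
    self-normalize its own CNV away.
    """
    if mean_coverage_per_bin <= 0:
        raise ValueError("mean coverage must be positive")
    rng = np.random.default_rng(seed)
    starts = np.arange(region[0], region[1], bin_size)
    cn = np.full(starts.size, 2, dtype=int)
    for span_start, span_end, copies in cn_profile:
        cn[(starts >= span_start) & (starts < span_end)] = copies
    raw = rng.poisson(mean_coverage_per_bin * cn / 2.0)
    baseline = float(np.median(rng.poisson(mean_coverage_per_bin, size=n_baseline_bins)))
    log2_ratio = np.log2(np.maximum(raw, 0.5) / baseline)
    return pd.DataFrame(
        {
            "contig": CONTIG,
            "bin_start": starts,
            "bin_end": np.minimum(starts + bin_size, region[1]),
            "raw_count": raw,
            "log2_ratio": log2_ratio,
        }
    )


_MAX_CN = 8


def _band_centers() -> np.ndarray:
    copies = np.arange(_MAX_CN + 1)
    return np.log2(np.maximum(copies, 0.5) / 2.0)


def segment_and_call(
    track: pd.DataFrame,
    *,
    tolerance: float = 0.25,
    min_bins: int = 4,
    median_window: int = 3,
) -> list[CnSegment]:
    """Median-smooth, classify bins to copy bands, merge runs into segments.

    Each smoothed bin is assigned the nearest copy band; runs shorter than
    ``min_bins`` are absorbed into their neighbors. The median filter
    correlates neighboring bins over its window, so noise excursions surface
    as runs about one window long whose level sits between bands; a run no
    longer than the window is therefore kept only when its mean lies within
    ``tolerance/2`` of its band center. Run boundaries are then refined
    against the unsmoothed track (least-squares changepoint between the two
    flanking band levels). Only non-2-copy segments are returned (a flat
    diploid track yields an empty list).
    """
    track = track.sort_values("bin_start").reset_index(drop=True)
    raw_log2 = track["log2_ratio"].to_numpy(float)
    log2 = median_filter(raw_log2, size=median_window, mode="nearest")
    centers = _band_centers()
    dist = np.abs(log2[:, None] - centers[None, :])
    cn = dist.argmin(axis=1)

    # Run-length encode, then absorb indeterminate and sub-minimum runs.
    runs: list[list] = []  # [cn, start_idx, end_idx (exclusive)]
    for i, value in enumerate(cn):
        if runs and runs[-1][0] == value:
            runs[-1][2] = i + 1
        else:
            runs.append([int(value), i, i + 1])

    def _mean_log2(run) -> float:
        return float(log2[run[1] : run[2]].mean())

    while len(runs) > 1:
        def _is_artifact(run) -> bool:
            length = run[2] - run[1]
            if run[0] == -1 or length < min_bins:
                return True
            if length <= median_window:
                return abs(_mean_log2(run) - centers[run[0]]) > 0.5 * tolerance
            return False

        bad = [idx for idx, run in enumerate(runs) if _is_artifact(run)]
        if not bad:
            break
        # Absorb the shortest offending run into the better-matching neighbor.
        idx = min(bad, key=lambda j: runs[j][2] - runs[j][1])
        run = runs[idx]
        neighbors = [j for j in (idx - 1, idx + 1) if 0 <= j < len(runs)]
        target = min(
            neighbors,
            key=lambda j: (
                abs(_mean_log2(run) - centers[runs[j][0]]) if runs[j][0] >= 0 else np.inf,
                -(runs[j][2] - runs[j][1]),
            ),
        )
        lo, hi = min(idx, target), max(idx, target)
        runs[lo] = [runs[target][0], runs[lo][1], runs[hi][2]]
        del runs[hi]
        # Merge newly adjacent equal-CN runs.
        merged = [runs[0]]
        for run in runs[1:]:
            if run[0] == merged[-1][0]:
                merged[-1][2] = run[2]
            else:
                merged.append(run)
        runs = merged

    # Reclassify each surviving run by its mean level: single bins near a
    # band edge can momentarily cross it, but a run's mean is stable.
    for run in runs:
        run[0] = int(np.argmin(np.abs(centers - _mean_log2(run))))
    merged = [runs[0]]
    for run in runs[1:]:
        if run[0] == merged[-1][0]:
            merged[-1][2] = run[2]
        else:
            merged.append(run)
    runs = merged

    # Refine each boundary on the unsmoothed track: place the changepoint
    # where the squared error against the two flanking band levels is
    # smallest (smoothing and absorption can drag an edge by a bin or two).
    for left, right in zip(runs, runs[1:]):
        c_left, c_right = centers[left[0]], centers[right[0]]
        jmin = max(left[1] + 1, left[2] - median_window)
        jmax = min(right[2] - 1, right[1] + median_window)
        if jmin > jmax:
            continue
        x = raw_log2[jmin:jmax]
        dl = (x - c_left) ** 2
        dr = (x - c_right) ** 2
        prefix_left = np.concatenate(([0.0], np.cumsum(dl)))
        suffix_right = np.concatenate((np.cumsum(dr[::-1])[::-1], [0.0]))
        best = jmin + int(np.argmin(prefix_left + suffix_right))
        left[2] = best
        right[1] = best

    starts = track["bin_start"].to_numpy()
    ends = track["bin_end"].to_numpy()
    segments = []
    for value, i, j in runs:
        copies = int(value) if value >= 0 else 2
        if copies != 2:
            segments.append(CnSegment(int(starts[i]), int(ends[j - 1]), copies))
    return segments


def segments_to_track(
    segments: Sequence[CnSegment],
    *,
    bin_size: int = BIN_SIZE,
    region: tuple[int, int] = REGION,
) -> pd.DataFrame:
    """Render segments back to a noise-free bin track (for idempotence checks)."""
    starts = np.arange(region[0], region[1], bin_size)
    cn = np.full(starts.size, 2, dtype=int)
    for seg in segments:
        cn[(starts >= seg.start) & (starts < seg.end)] = seg.copy_number
    return pd.DataFrame(
        {
            "contig": CONTIG,
            "bin_start": starts,
            "bin_end": np.minimum(starts + bin_size, region[1]),
            "raw_count": cn * 50,
            "log2_ratio": np.log2(np.maximum(cn, 0.5) / 2.0),
        }
    )


def _snap(position: int, bp_map: Mapping[str, int], window: int) -> str | None:
    label = min(bp_map, key=lambda name: abs(bp_map[name] - position))
    return label if abs(bp_map[label] - position) <= window else None


def assign_breakpoints(
    segments: Sequence[CnSegment],
    bp_map: Mapping[str, int] | None = None,
    *,
    window: int = 500_000,
    methylation_band: str | None = None,
    imprinted_center: int = IMPRINTED_CENTER,
) -> SubtypeCall:
    """Snap segment boundaries to BP1-BP5 and type the chromosome 15 event.

    Deletions and interstitial duplications report both boundaries of each
    segment; supernumerary events (idic15, tricentric) report only distal
    (segment-end) breakpoints — the proximal extent of an isodicentric
    chromosome runs into centromeric material and is not BP-mediated.
    Deletion subtypes need the first-tier methylation band to name the
    syndrome: ``low`` -> AS, ``high`` -> PWS.
    """
    bp_map = dict(BP_MAP if bp_map is None else bp_map)
    missing = {f"BP{i}" for i in range(1, 6)} - set(bp_map)
    if missing:
        raise ValueError(f"bp_map is missing {sorted(missing)}")
    if not segments:
        return SubtypeCall("normal", (), 2)

    center_cn = 2
    center_segment = None
    for seg in segments:
        if seg.start <= imprinted_center < seg.end:
            center_cn = seg.copy_number
            center_segment = seg

    def snap_many(positions):
        labels, raw = [], []
        for pos in positions:
            label = _snap(pos, bp_map, window)
            (labels.append(label) if label else raw.append(pos))
        return labels, raw

    supernumerary = center_cn >= 4
    if supernumerary:
        boundary_positions = [seg.end for seg in segments]
    else:
        boundary_positions = [pos for seg in segments for pos in (seg.start, seg.end)]
    labels, unsnapped = snap_many(boundary_positions)
    bps = tuple(sorted(set(labels)))

    if center_cn == 1 and center_segment is not None:
        del_bps, _ = snap_many([center_segment.start, center_segment.end])
        del_set = set(del_bps)
        if del_set == {"BP1", "BP3"}:
            del_type = "typeI"
        elif del_set == {"BP2", "BP3"}:
            del_type = "typeII"
        else:
            del_type = None
        syndrome = {"low": "AS", "high": "PWS"}.get(methylation_band or "")
        if del_type and syndrome:
            label = f"{syndrome}_del_{del_type}"
        else:
            label = "unclassified"
    elif center_cn == 3:
        label = "interstitial_dup"
    elif center_cn == 4:
        label = "idic15"
    elif center_cn >= 6:
        label = "tricentric"
    else:
        label = "unclassified"
    return SubtypeCall(label, bps, center_cn, tuple(sorted(unsnapped)))
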