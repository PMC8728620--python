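# Methods

This note documents the models behind each module, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic data does and does not establish.

## Parent-of-origin model and genotype classes

The *SNRPN* promoter is methylated on the maternal and unmethylated on the
paternal allele, so a genotype's true methylation fraction is
(methylated maternal copies)/(total copies): control 1/2, PWS 1 (paternal
loss by deletion, maternal UPD, or imprinting defect), AS 0, maternal
interstitial duplication 2/3, idic15 3/4, tricentric 5/7. A mosaic carries
the abnormal genotype in a fraction f of cells; its effective methylation is
f·m + (1−f)·0.5, always in [0,1]. AS caused by a *UBE3A* point mutation
keeps m = 0.5 and exists in the class registry (default prevalence 0) as the
screen's structural blind spot: no methylation-based tier can see it.

Copy-number profiles use GRCh37 (NC_000015.9) coordinates on the modeled
window chr15:20.00–35.00 Mb with breakpoint anchors BP1 22.30, BP2 23.10,
BP3 28.30, BP4 30.30, BP5 32.25 Mb (approximate, config-overridable).
Deletions default to type II (BP2–BP3); the idic15 profile is CN=4 over
22.55–30.10 Mb with a CN=3 shoulder 30.30–32.25 Mb; the tricentric class
defaults to CN=7 over the imprinted region with methylation 5/7 — its
methylation is a model assumption from the parent-of-origin arithmetic, not
an observed value.

## First-tier assay model (cohort dispersion)

Control melt ratios are drawn from a truncated Normal(0.51, 0.085): the SD
is fixed so that 3·SD = 0.255, making the ±3SD normal range 0.255–0.765.
Archival storage adds a heavy-tailed artifact mixture: with weight
w(years) = 0.052·(1 − e^(−years/2.5)), a sample's value is replaced by
0.51 + 0.12·t_df, with df = max(3, 30/(1+years)). At the default 5 years of
storage this yields ~0.5% of controls outside the ±3SD range and a sample
SD near 0.089 — tails broaden with storage age (kurtosis is nondecreasing in
storage years) while the mean and SD stay near the fresh-sample values.

Affected classes are modeled as tight clusters (SD 0.008) about their class
methylation. Two deliberate choices here define the separation margins of
the default study conditions:

* **Duplication melt bias (+0.05).** Duplication genotypes read high on the
  melt tier relative to the parent-of-origin expectation, placing an idic15
  at ≈ 0.80. This is the mechanism by which the ±3SD rule detects an idic15
  (0.80 > upper bound ≈ 0.78) while the conservative 0.88 band does not; a
  bias-free idic15 at 0.75 would sit within a fraction of an SD of the 3SD
  bound and its detection would be a coin flip rather than a property of the
  thresholds. The droplet tier reads the true 0.75 — the bias is a
  melt-assay effect, not a biological one — so the two tiers stay
  mechanistically distinct.
* **Artifact tails apply to controls only** (`affected_tails=False` by
  default). The tail mixture models melt artifacts of degraded
  normal-methylation DNA; keeping proband signals artifact-free gives the
  workflow's default conditions guaranteed separation, which is what the
  end-to-end reproduction asserts. Set `affected_tails=True` to study the
  degraded-proband case.

## Melt forward model and quantifier

F(T) = m·S(T; Tm_meth) + (1−m)·S(T; Tm_unmeth) + ε, with S a decreasing
logistic, Tm_unmeth = 78 °C, Tm_meth = 82 °C (ΔTm 4 °C), width 0.35 °C,
grid 65–95 °C at 0.1 °C, fluorescence noise SD 0.003. The quantifier
computes −dF/dT with a Savitzky-Golay filter (window 11, order 3, derivative
in one pass), finds the two most prominent transition peaks, splits the
cumulative-trapezoid area at the valley between them, and reports the
high-Tm fraction. A single-transition curve is split at the midpoint between
the model Tms (the tie-break) and flagged `single_peak` instead of raising.
Integration is not rectified: zero-mean noise then cancels in the
telescoping integral rather than accumulating as positive area.

With these widths the raw fraction is linear in m up to ~2% cross-peak
leakage; spiked standards at {0, 0.25, 0.5, 0.75, 1} fit a straight line
(isotonic regression is the fallback when residuals exceed 0.02), and the
calibrated noise-free round-trip error is < 0.003 across a 21-point grid.
Per-plate run shifts are estimated from a mid-range (0.5) spike-standard
well — boundary controls (PWS ≈ 1, AS ≈ 0) saturate and cannot sense a
shift — and subtracted; plates without control wells are rejected; an
estimated |shift| > 0.05 sets a `plate_shift` QC flag. The whole-cohort
path vectorizes curve simulation and quantification (a 16 579-sample screen
runs in ~2 s) and agrees with the per-curve peak-finding path to < 0.02.

## Tier-1 thresholds

`sd_rule`: lower/upper = mean ∓ k·SD of the screened distribution (plain
sample moments, ddof 1 — the published range is computed on the full
distribution, tails included; a median/MAD option exists behind `robust=`).
Flagging is strictly outside. `conservative`: AS band ≤ 0.12, PWS band
≥ 0.88, inclusive, matching the printed operators; the bands must nest
inside the sd_rule range, so every conservative positive is an sd_rule
positive. Estimating a normal range requires ≥ 100 samples; the pipeline
falls back to the published fixed values (0.51, 0.085) for smaller batches.
Percent referred is rendered half-away-from-zero to 2 decimals
(92/16 579 → 0.55%).

## Droplet digital PCR (tier 2, methylation)

The competitive-priming chemistry is abstracted to an unbiased two-channel
droplet measurement: channel loads m·λ and (1−m)·λ copies/droplet, negative
counts are Binomial(N, e^(−load)), and λ̂ = −ln(neg/total). Defaults:
λ = 1 copy/droplet, N = 20 000 droplets. All droplets positive raises a
saturation error that propagates as a QC failure, never a confirmed call.
The ratio λ̂_m/(λ̂_m+λ̂_u) is evaluated so that swapping channels maps it to
its exact floating-point complement. The reference range is the min/max of
20 storage-matched control wells (a mean ± k·SD option exists); the panel is
modeled with a wider between-sample spread (SD 0.02) than the screened
controls' biological spread (SD 0.003) because it is *selected* to span the
cohort's storage and quality extremes — a min/max range over 20 wells
exchangeable with the flagged samples would spuriously confirm ~2 of every
21 flagged controls, which is not how a bounding reference panel behaves.
Absolute copies/µL uses an assumed 0.85 nL droplet volume (convenience
output only; every decision uses ratios).

## CNV qPCR (tier 2, copy number)

Quantities come from per-assay standard curves Ct ~ log10(quantity)
(passing: efficiency 10^(−1/slope) − 1 in (0.8, 1.1), r² ≥ 0.98), and the
CNV ratio is 2·bias·q_SNRPN/q_βglobin. The empirical 2-copy range
(1.62–2.02) is not centered at 2, which is modeled as a global assay scale
bias = 0.91 (range midpoint over 2); the 1-copy range (0.97–1.26) sits off
that scale again, handled as a per-copy response factor (deletion templates
respond at 1.115 per copy). Per-reaction Ct noise is 0.15 cycles, dominated
by a shared sample-loading component that cancels under normalization;
the independent per-channel residual is 0.03 cycles — the published ±11%
2-copy range and near-perfect class separation are only simultaneously
possible when most of the per-well noise is shared. Ranges for 4, 5 and 7
copies are **not published values**: defaults are the class centre ×/÷
2^(3.5·σ_log2) with σ_log2 = √2·0.03, deterministic and non-overlapping.
Membership is inclusive at both endpoints; gaps are indeterminate; results
in the deletion or tricentric ranges, below all ranges, or above the 5-copy
range are flagged for LC-WGS reflex. One punch per sample is modeled (no
replicate averaging by default).

## LC-WGS (tier 3)

Reads per 50 kb bin are Poisson(coverage·CN/2), normalized to the median of
2000 co-simulated diploid baseline bins — normalizing within the window
would let a mostly-duplicated chromosome self-normalize its CNV away — and
floored at 0.5 counts before log2 (avoiding −∞). Segmentation: median
filter (window 3 bins), per-bin assignment to the nearest copy band
(log2(CN/2), CN 0–8), run-length encoding, absorption of runs shorter than
`min_bins` = 4, and a consistency rule for runs no longer than the filter
window (the filter correlates neighbors, so noise excursions surface as
window-length runs *between* bands: they are kept only when their mean is
within tolerance/2 = 0.125 of their band center). Runs are then
reclassified by their mean level and each boundary is refined against the
unsmoothed track by least-squares changepoint search within ± window bins.
At 100 reads/bin this recovers the modeled deletion and idic15 boundaries
to ±1 bin in ≈ 95% of seeds, and the subtype and breakpoint calls below in
100% of 300 test seeds; GC correction is out of scope for the simulator
(uniform bins), with the interface accepting any externally produced track.

Subtypes come from the copy number over the imprinted center (SNRPN,
25.2 Mb): CN=1 is a deletion, typed by its snapped breakpoints (BP1–BP3
type I, BP2–BP3 type II) and named AS or PWS by the tier-1 methylation band
(low/high); CN=3 an interstitial duplication; CN=4 idic15; CN≥6 tricentric.
Boundary snapping uses a 500 kb window. Supernumerary events (idic15,
tricentric) report only distal (segment-end) breakpoints: the proximal
extent of an isodicentric chromosome runs into pericentromeric material and
is not a BP-mediated exchange point, which is why an idic15 reports
{BP4, BP5} even though its proximal CN=4 edge lies near BP1. Internal
coordinates are 0-based half-open; HGVS g. strings are 1-based inclusive,
and the conversion is an exact bijection.

## Screening statistics

PPV = confirmed/flagged; per-condition PPV denominators use the flagged
count in the condition's own tier-1 band (low for AS, high for PWS and
Dup15q) when band information is available — the published per-condition
denominators under the ±3SD thresholds are not derivable from the report's
own tier flow otherwise. Prevalence = confirmed/screened with "1 in N"
rendering (N half-away-from-zero; thousands grouped with spaces from five
digits: "1 in 16 579"). Confidence intervals are exact Clopper-Pearson via
beta quantiles, which the tests verify against brute-force binomial tail
inversion to 1e-9; k = 0 uses the closed-form upper bound 1 − (α/2)^(1/n).
Percents render half-away-from-zero to 1 decimal (2 decimals for sub-1%
rates). Tier flow enforces the conservation identities
screened = negative + flagged and flagged = confirmed + unconfirmed +
QC-failed.

## Pipeline and reproducibility

`RunConfig` is schema-validated before any computation; every stochastic
stage receives a sub-seed derived from the master seed, so a config
reproduces its report byte-identically. Tier 2 runs on the union of both
threshold modes' flags (the conservative set nests inside the sd set), and
the report carries both flows. Tier 3 runs on methylation-confirmed samples
whose CNV class is non-diploid or extreme — the published workflow reflexed
only the two most extreme CNV outliers for material reasons; routing every
confirmed non-diploid result to WGS typing is this pipeline's default
because simulated material is free. Artifacts: TSV sample sheet (latent
truth in `truth_`-prefixed columns that the masked reader strips), TSV call
tables, BED (0-based half-open) plus an HGVS sidecar TSV (1-based inclusive)
for segments, JSON report with a config-hash provenance block, and one
structured log line per stage with in/out counts.

## Problem sizes and runtime

Defaults were chosen so the full population run is routine on a laptop: the
16 579-sample screen with both threshold modes completes in ~2–3 s, the
whole test suite in ~5 s, and the acceptance script in ~3 s. The larger
Monte-Carlo checks (200×100 000-droplet wells, 2500 CNV classifications,
2000-draw CI coverage) are sized to give ≥3σ separation on the properties
they assert.

## What the synthetic cohort does and does not show

The generator reproduces the *statistical structure* the workflow assumes:
a 0.51/0.085 control distribution with storage-dependent tails, exact rare-
case counts, per-tier noise with documented separation margins. Passing
tests therefore demonstrate that the algorithms are correct and the tier
logic behaves as designed under those conditions. They do not validate the
assay chemistry, the real false-negative rate (deidentified screening
cannot observe it), real per-copy qPCR response, GC or mappability structure
in sequencing data, or the published validation-cohort sensitivities and
PPVs, which depend on archived patient samples. The duplication melt bias
and the reference-panel spread are model choices on exactly this boundary:
they encode the reported qualitative behavior (idic15 detected by ±3SD but
not by conservative bands; zero spurious ddPCR confirmations among ~90
flagged controls) as defaults, rather than deriving it from first
principles.

## Known limitations

* UPD/imprinting-defect cases are indistinguishable from deletions at tier 1
  and from controls at the CNV tiers by design; only the deletion/duplication
  subtypes get a WGS type.
* Mosaic PWS with low mosaic fractions drifts toward 0.5 and can be missed —
  faithful to the screen's physics.
* The melt model is two-transition only; heteroduplex or multi-domain melt
  shapes are out of scope.
* Copy-class ranges above 2 copies and the 5/7-copy reflex cut are
  model-derived, not empirical.
* Segmentation assumes uniform bins; real tracks need GC/mappability
  correction upstream.
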