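"""Methylation-specific quantitative melt analysis (MS-QMA), simulated and quantified.

Forward model: after bisulfite conversion, unmethylated template is AT-richer
and melts earlier than methylated template, so the fluorescence of a
post-PCR melt is a two-transition decay

    F(T) = m * S(T; Tm_meth) + (1 - m) * S(T; Tm_unmeth) + noise,

with S a decreasing sigmoid and Tm_unmeth < Tm_meth. The quantifier works on
the negative smoothed derivative -dF/dT: it locates the valley between the
two transition peaks and returns the high-temperature (methylated) peak area
as a fraction of the total peak area. Spiked standards of known methylated
fraction calibrate that raw area fraction onto the methylation-ratio scale,
and per-plate control wells correct run-to-run shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks, savgol_filter
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "MeltModel",
    "MeltCurve",
    "CalibrationSet",
    "MethylationCall",
    "CalibrationError",
    "PlateError",
    "default_grid",
    "simulate_melt",
    "simulate_melt_batch",
    "raw_area_fraction",
    "raw_area_fraction_batch",
    "fit_calibration",
    "make_standards",
    "quantify_plate",
    "measure_cohort",
]


class CalibrationError(ValueError):
    """Spiked-standard calibration could not produce a monotone map."""


class PlateError(ValueError):
    """A plate is missing the control wells needed for shift correction."""


@dataclass(frozen=True)
class MeltModel:
    """Two-transition melt physics: transition midpoints and width in deg C."""

    tm_unmeth: float = 78.0
    tm_meth: float = 82.0  # delta-Tm 4 deg C between converted templates
    width: float = 0.35
    grid_start: float = 65.0
    grid_stop: float = 95.0
    grid_step: float = 0.1
    smooth_window: int = 11
    smooth_order: int = 3


DEFAULT_MODEL = MeltModel()


def default_grid(model: MeltModel = DEFAULT_MODEL) -> np.ndarray:
    n = int(round((model.grid_stop - model.grid_start) / model.grid_step)) + 1
    return model.grid_start + model.grid_step * np.arange(n)


@dataclass
class MeltCurve:
    temperatures: np.ndarray
    fluorescence: np.ndarray
    well_id: str = ""
    plate_id: str = ""
    role: str = "sample"  # sample | pws_control | as_control | spike_standard
    known_mix: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.temperatures.size < 50:
            raise ValueError("melt grid needs at least 50 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence lengths differ")


@dataclass(frozen=True)
class MethylationCall:
    sample_id: str
    ratio: float
    method: str = "MSQMA"
    plate_id: str = ""
    qc_flags: tuple = ()


def _sigmoid_decay(temps: np.ndarray, tm: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((temps - tm) / width))


def simulate_melt_batch(
    methylation: np.ndarray,
    *,
    noise_sd: float = 0.0,
    seed: int | None = None,
    model: MeltModel = DEFAULT_MODEL,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Fluorescence matrix (one row per well) for a vector of methylated fractions."""
    m = np.atleast_1d(np.asarray(methylation, float))[:, None]
    if np.any((m < 0) | (m > 1)):
        raise ValueError("methylation must be in [0,1]")
    temps = default_grid(model) if grid is None else np.asarray(grid, float)
    if not np.all(np.diff(temps) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    fluor = m * _sigmoid_decay(temps, model.tm_meth, model.width) + (
        1.0 - m
    ) * _sigmoid_decay(temps, model.tm_unmeth, model.width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fluor = fluor + noise_sd * rng.standard_normal(fluor.shape)
    return fluor


def simulate_melt(
    methylation: float,
    *,
    noise_sd: float = 0.0,
    seed: int | None = None,
    model: MeltModel = DEFAULT_MODEL,
    grid: np.ndarray | None = None,
    well_id: str = "",
    plate_id: str = "",
    role: str = "sample",
    known_mix: float | None = None,
) -> MeltCurve:
    """Simulate one melt curve for a given methylated template fraction."""
    temps = default_grid(model) if grid is None else np.asarray(grid, float)
    fluor = simulate_melt_batch(
        [methylation], noise_sd=noise_sd, seed=seed, model=model, grid=temps
    )[0]
    return MeltCurve(temps, fluor, well_id, plate_id, role, known_mix)


def _smoothed_neg_derivative(
    fluor2d: np.ndarray, temps: np.ndarray, model: MeltModel
) -> np.ndarray:
    step = float(np.median(np.diff(temps)))
    window = min(model.smooth_window, fluor2d.shape[-1] // 2 * 2 - 1)
    return -savgol_filter(
        fluor2d, window, model.smooth_order, deriv=1, delta=step, axis=-1
    )


def _area_split(deriv: np.ndarray, temps: np.ndarray, valley_idx: np.ndarray) -> np.ndarray:
    """High-temperature peak area / total area, splitting each row at its valley.

    Integration is done on the raw smoothed derivative (no rectification):
    zero-mean fluorescence noise then cancels in the telescoping integral
    instead of accumulating as rectified positive area.
    """
    cum = cumulative_trapezoid(deriv, temps, axis=-1, initial=0.0)
    total = cum[:, -1]
    rows = np.arange(deriv.shape[0])
    high_area = total - cum[rows, valley_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 1e-6, high_area / total, 0.5)
    return np.clip(frac, 0.0, 1.0)


def raw_area_fraction_batch(
    fluor2d: np.ndarray,
    temps: np.ndarray,
    model: MeltModel = DEFAULT_MODEL,
) -> np.ndarray:
    """Vectorized quantifier: valley searched between the model transition Tms.

    Used for whole-cohort runs; agrees with the peak-finding path of
    :func:`raw_area_fraction` on two-transition curves.
    """
    deriv = _smoothed_neg_derivative(np.atleast_2d(fluor2d), temps, model)
    lo = int(np.searchsorted(temps, model.tm_unmeth))
    hi = int(np.searchsorted(temps, model.tm_meth))
    valley = lo + np.argmin(deriv[:, lo : hi + 1], axis=-1)
    return _area_split(deriv, temps, valley)


def raw_area_fraction(
    curve: MeltCurve,
    model: MeltModel = DEFAULT_MODEL,
    *,
    return_flags: bool = False,
):
    """Methylated (high-Tm) derivative-peak area as a fraction of total area.

    Two transition peaks are located on the smoothed -dF/dT trace; the area
    above the valley between them, over the total, is the raw ratio. A
    single-transition curve is split at the midpoint between the two model
    Tms (the configured tie-break) and carries a ``single_peak`` qc flag
    rather than raising: it quantifies to ~0 or ~1 by construction.
    """
    temps = curve.temperatures
    deriv = _smoothed_neg_derivative(curve.fluorescence[None, :], temps, model)[0]
    height = float(deriv.max())
    flags: list[str] = []
    if height <= 1e-9:
        frac = 0.5
        flags.append("flat_curve")
    else:
        peaks, props = find_peaks(deriv, prominence=0.02 * height)
        if peaks.size >= 2:
            top2 = peaks[np.argsort(props["prominences"])[-2:]]
            left, right = int(top2.min()), int(top2.max())
            valley = left + int(np.argmin(deriv[left : right + 1]))
        else:
            midpoint = 0.5 * (model.tm_unmeth + model.tm_meth)
            valley = int(np.searchsorted(temps, midpoint))
            flags.append("single_peak")
        frac = float(_area_split(deriv[None, :], temps, np.array([valley]))[0])
    if return_flags:
        return frac, tuple(flags)
    return frac


@dataclass
class CalibrationSet:
    """Monotone map from raw melt area fraction to calibrated methylation ratio."""

    known_mix: np.ndarray  # sorted known methylated fractions of the standards
    raw_measured: np.ndarray  # measured raw area fraction at each level
    fitted_raw: np.ndarray  # monotone (isotonic or linear) fit of raw vs known
    kind: str = "linear"  # linear | isotonic

    def apply(self, raw):
        """Raw area fraction -> calibrated methylation ratio in [0,1]."""
        cal = np.interp(np.asarray(raw, float), self.fitted_raw, self.known_mix)
        return np.clip(cal, 0.0, 1.0)

    def inverse(self, ratio):
        """Calibrated ratio -> expected raw area fraction."""
        return np.interp(np.asarray(ratio, float), self.known_mix, self.fitted_raw)


def fit_calibration(
    standards: Sequence[MeltCurve],
    model: MeltModel = DEFAULT_MODEL,
    *,
    monotone_tolerance: float = 0.05,
    linear_residual_tolerance: float = 0.02,
) -> CalibrationSet:
    """Fit the spiked-standard calibration from curves with known methylated mix.

    Requires at least 3 distinct spike levels including 0 and 1. Fits a
    straight line when residuals permit (the forward model is linear in the
    methylated fraction), falling back to isotonic regression plus linear
    interpolation otherwise.
    """
    pairs = [
        (float(c.known_mix), raw_area_fraction(c, model))
        for c in standards
        if c.known_mix is not None
    ]
    if not pairs:
        raise CalibrationError("no standards with known_mix supplied")
    levels = sorted({k for k, _ in pairs})
    if len(levels) < 3 or levels[0] != 0.0 or levels[-1] != 1.0:
        raise CalibrationError(
            "calibration needs >= 3 distinct spike levels including 0 and 1"
        )
    known = np.array(levels)
    raw = np.array(
        [np.mean([r for k, r in pairs if k == level]) for level in levels]
    )
    drops = np.diff(raw)
    if np.any(drops < -monotone_tolerance):
        raise CalibrationError(
            f"measured standards are non-monotone beyond tolerance: {raw.tolist()}"
        )

    slope, intercept = np.polyfit(known, raw, 1)
    linear_fit = intercept + slope * known
    if slope > 0 and np.max(np.abs(linear_fit - raw)) <= linear_residual_tolerance:
        return CalibrationSet(known, raw, linear_fit, kind="linear")
    iso = IsotonicRegression(increasing=True)
    iso_fit = iso.fit_transform(known, raw)
    # Break exact ties so the inverse interpolation stays well defined.
    iso_fit = np.maximum.accumulate(iso_fit + 1e-9 * np.arange(len(iso_fit)))
    return CalibrationSet(known, raw, iso_fit, kind="isotonic")


DEFAULT_SPIKE_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


def make_standards(
    levels: Sequence[float] = DEFAULT_SPIKE_LEVELS,
    *,
    noise_sd: float = 0.0,
    seed: int | None = None,
    model: MeltModel = DEFAULT_MODEL,
    plate_id: str = "CAL",
) -> list[MeltCurve]:
    """Simulate a spiked-standard dilution series (PWS/AS DNA mixed at known ratios)."""
    rng = np.random.default_rng(seed)
    return [
        simulate_melt(
            level,
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)) if noise_sd > 0 else None,
            model=model,
            well_id=f"STD{i}",
            plate_id=plate_id,
            role="spike_standard",
            known_mix=level,
        )
        for i, level in enumerate(levels)
    ]


_CONTROL_EXPECTED = {"pws_control": 1.0, "as_control": 0.0}


def quantify_plate(
    curves: Sequence[MeltCurve],
    calibration: CalibrationSet,
    model: MeltModel = DEFAULT_MODEL,
    *,
    shift_qc_tolerance: float = 0.05,
) -> list[MethylationCall]:
    """Quantify one plate: calibrate raw areas, then shift-correct on controls.

    The plate shift is the mean (observed - expected) calibrated ratio over
    control wells whose expected value is away from the 0/1 boundaries
    (saturating controls cannot sense a shift); plates without control wells
    are rejected. Calls are returned for sample wells only.
    """
    expected = []
    observed = []
    n_controls = 0
    for c in curves:
        exp = (
            c.known_mix
            if c.role == "spike_standard"
            else _CONTROL_EXPECTED.get(c.role)
        )
        if c.role != "sample":
            n_controls += 1
        if exp is not None and 0.05 < exp < 0.95:
            expected.append(exp)
            observed.append(float(calibration.apply(raw_area_fraction(c, model))))
    if n_controls == 0:
        raise PlateError("plate has no control wells; plate rejected")
    shift = float(np.mean(np.array(observed) - np.array(expected))) if expected else 0.0
    plate_flags = ("plate_shift",) if abs(shift) > shift_qc_tolerance else ()

    calls = []
    for c in curves:
        if c.role != "sample":
            continue
        raw, flags = raw_area_fraction(c, model, return_flags=True)
        ratio = float(np.clip(calibration.apply(raw) - shift, 0.0, 1.0))
        calls.append(
            MethylationCall(
                sample_id=c.well_id,
                ratio=ratio,
                method="MSQMA",
                plate_id=c.plate_id,
                qc_flags=flags + plate_flags,
            )
        )
    return calls


def measure_cohort(
    methylation: np.ndarray,
    plate_ids: Sequence[str],
    calibration: CalibrationSet,
    *,
    seed: int,
    noise_sd: float = 0.003,
    plate_shift_sd: float = 0.005,
    model: MeltModel = DEFAULT_MODEL,
    shift_qc_tolerance: float = 0.05,
) -> np.ndarray:
    """Whole-cohort first-tier measurement: melt, quantify, calibrate, shift-correct.

    Vectorized equivalent of building every plate's curves and calling
    :func:`quantify_plate`: each plate receives a random run shift applied to
    all its wells plus a mid-range spike standard well used to estimate and
    remove that shift. Returns calibrated ratios aligned with the input.
    """
    methylation = np.asarray(methylation, float)
    plate_ids = np.asarray(plate_ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3317]))
    temps = default_grid(model)

    unique_plates, plate_idx = np.unique(plate_ids, return_inverse=True)
    shifts = plate_shift_sd * rng.standard_normal(unique_plates.size)

    # Sample wells plus one 0.5 spike-standard sensor well per plate.
    m_wells = np.concatenate([methylation + shifts[plate_idx], np.full(unique_plates.size, 0.5) + shifts])
    m_wells = np.clip(m_wells, 0.0, 1.0)
    fluor = simulate_melt_batch(m_wells, noise_sd=noise_sd, seed=int(rng.integers(2**31)), model=model, grid=temps)
    raw = raw_area_fraction_batch(fluor, temps, model)
    calibrated = calibration.apply(raw)

    sensor = calibrated[methylation.size :]
    est_shift = sensor - 0.5
    corrected = calibrated[: methylation.size] - est_shift[plate_idx]
    return np.clip(corrected, 0.0, 1.0)
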