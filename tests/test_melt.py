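"""Melt forward model and derivative-peak-area quantifier."""

import numpy as np
import pytest

from imprint15 import cohort, melt


class TestForwardModel:
    def test_pure_methylated_is_single_high_tm_transition(self):
        curve = melt.simulate_melt(1.0)
        frac, flags = melt.raw_area_fraction(curve, return_flags=True)
        assert "single_peak" in flags
        assert frac > 0.99

    def test_pure_unmethylated_is_single_low_tm_transition(self):
        frac, flags = melt.raw_area_fraction(melt.simulate_melt(0.0), return_flags=True)
        assert "single_peak" in flags
        assert frac < 0.01

    def test_half_methylated_splits_areas_equally(self):
        frac = melt.raw_area_fraction(melt.simulate_melt(0.5))
        assert frac == pytest.approx(0.5, abs=1e-6)

    def test_melt_is_monotone_decay(self):
        curve = melt.simulate_melt(0.3)
        assert np.all(np.diff(curve.fluorescence) <= 1e-12)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            melt.simulate_melt(0.5, grid=np.linspace(95, 65, 100))

    def test_reproducible_under_seed(self):
        a = melt.simulate_melt(0.4, noise_sd=0.01, seed=3)
        b = melt.simulate_melt(0.4, noise_sd=0.01, seed=3)
        assert np.array_equal(a.fluorescence, b.fluorescence)


class TestQuantifier:
    def test_noise_free_round_trip(self):
        # Forward-model oracle: quantifying a simulated curve must recover
        # the methylated fraction it was built from.
        assert melt.raw_area_fraction(melt.simulate_melt(0.3)) == pytest.approx(0.30, abs=0.02)

    def test_calibrated_round_trip_within_tolerance_and_monotone(self, calibration):
        grid = np.linspace(0.0, 1.0, 21)
        estimates = calibration.apply(
            [melt.raw_area_fraction(melt.simulate_melt(m)) for m in grid]
        )
        assert np.max(np.abs(estimates - grid)) <= 0.02
        assert np.all(np.diff(estimates) >= -1e-9)

    def test_batch_quantifier_agrees_with_peak_finding_path(self):
        grid = np.linspace(0.05, 0.95, 19)
        temps = melt.default_grid()
        batch = melt.raw_area_fraction_batch(melt.simulate_melt_batch(grid), temps)
        single = np.array([melt.raw_area_fraction(melt.simulate_melt(m)) for m in grid])
        assert np.max(np.abs(batch - single)) < 0.02


class TestCalibration:
    def test_negligible_leakage_standards_give_identity_map(self):
        # Widely separated transitions make raw == known, so the fitted map
        # must be the identity to numerical precision.
        model = melt.MeltModel(tm_unmeth=75.0, tm_meth=85.0, width=0.25)
        standards = melt.make_standards(model=model)
        cal = melt.fit_calibration(standards, model)
        assert cal.kind == "linear"
        assert np.max(np.abs(cal.apply(cal.known_mix) - cal.known_mix)) < 1e-6

    def test_amplification_bias_is_calibrated_away(self):
        # Multiplicative efficiency bias b distorts the encoded fraction to
        # b*m / (b*m + 1 - m); standards with the same bias must undo it.
        b = 1.2

        def biased(m):
            return b * m / (b * m + 1.0 - m)

        levels = (0.0, 0.25, 0.5, 0.75, 1.0)
        standards = [
            melt.simulate_melt(biased(level), role="spike_standard", known_mix=level)
            for level in levels
        ]
        cal = melt.fit_calibration(standards, linear_residual_tolerance=0.005)
        truth = np.linspace(0.0, 1.0, 11)
        recovered = cal.apply(
            [melt.raw_area_fraction(melt.simulate_melt(biased(m))) for m in truth]
        )
        assert np.max(np.abs(recovered - truth)) <= 0.02

    def test_two_levels_rejected(self):
        standards = melt.make_standards(levels=(0.0, 1.0))
        with pytest.raises(melt.CalibrationError, match="3 distinct"):
            melt.fit_calibration(standards)

    def test_must_include_both_endpoints(self):
        standards = melt.make_standards(levels=(0.0, 0.3, 0.6))
        with pytest.raises(melt.CalibrationError):
            melt.fit_calibration(standards)


def _plate(methylations, shift=0.0, plate_id="P1"):
    curves = [
        melt.simulate_melt(np.clip(m + shift, 0, 1), well_id=f"W{i}", plate_id=plate_id)
        for i, m in enumerate(methylations)
    ]
    controls = [
        melt.simulate_melt(np.clip(1.0 + shift, 0, 1), role="pws_control", plate_id=plate_id),
        melt.simulate_melt(np.clip(0.0 + shift, 0, 1), role="as_control", plate_id=plate_id),
        melt.simulate_melt(
            np.clip(0.5 + shift, 0, 1), role="spike_standard", known_mix=0.5, plate_id=plate_id
        ),
    ]
    return curves + controls


class TestPlateQuantification:
    def test_zero_deviation_plate_returns_calibrated_values(self, calibration):
        truth = [0.2, 0.5, 0.8]
        calls = melt.quantify_plate(_plate(truth), calibration)
        assert len(calls) == 3
        for call, m in zip(calls, truth):
            assert call.ratio == pytest.approx(m, abs=0.01)
            assert "plate_shift" not in call.qc_flags

    def test_uniform_shift_recovered_by_controls(self, calibration):
        truth = [0.3, 0.5, 0.7]
        calls = melt.quantify_plate(_plate(truth, shift=0.05), calibration)
        for call, m in zip(calls, truth):
            assert call.ratio == pytest.approx(m, abs=0.01)

    def test_large_shift_sets_qc_flag(self, calibration):
        calls = melt.quantify_plate(_plate([0.5], shift=0.08), calibration)
        assert "plate_shift" in calls[0].qc_flags

    def test_plate_without_controls_rejected(self, calibration):
        curves = [melt.simulate_melt(0.5, well_id="W0")]
        with pytest.raises(melt.PlateError, match="rejected"):
            melt.quantify_plate(curves, calibration)

    def test_full_plate_accounting(self, calibration):
        plate = _plate(np.linspace(0.2, 0.8, 93).tolist())
        assert len(plate) == 96
        assert len(melt.quantify_plate(plate, calibration)) == 93


class TestCohortMeasurement:
    def test_control_population_matches_printed_distribution(self, calibration):
        # 10 000 archival controls through the full melt path must reproduce
        # the screening distribution (mean 0.51, SD 0.085) within 0.01.
        controls = cohort.make_cohort(10_000, {}, seed=13)
        m = cohort.draw_melt_methylation(controls, seed=13)
        ratios = melt.measure_cohort(
            m, [s.plate_id for s in controls], calibration, seed=13
        )
        assert abs(ratios.mean() - 0.51) < 0.01
        assert abs(ratios.std(ddof=1) - 0.085) < 0.01

    def test_injected_plate_shift_corrected(self, calibration):
        m = np.full(50, 0.5)
        shifted = melt.measure_cohort(
            m, ["P1"] * 50, calibration, seed=1, noise_sd=0.0, plate_shift_sd=0.04
        )
        assert np.max(np.abs(shifted - 0.5)) < 0.01
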