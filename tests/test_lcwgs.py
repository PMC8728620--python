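"""Low-coverage WGS bin simulation, segmentation, and subtype assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprint15 import lcwgs

DELETION = [(23_100_000, 28_300_000, 1)]  # BP2-BP3, 15q11.2-q13
IDIC15 = [(22_550_000, 30_100_000, 4), (30_300_000, 32_250_000, 3)]


class TestSimulateBins:
    def test_diploid_baseline_centers_at_zero(self):
        track = lcwgs.simulate_bins([], 100.0, seed=1)
        assert abs(np.median(track["log2_ratio"])) <= 0.05

    def test_expected_log2_levels(self):
        track = lcwgs.simulate_bins(DELETION + [(30_000_000, 33_000_000, 3)], 200.0, seed=2)
        in_del = (track.bin_start >= 23_100_000) & (track.bin_start < 28_300_000)
        in_dup = (track.bin_start >= 30_000_000) & (track.bin_start < 33_000_000)
        assert np.mean(track.log2_ratio[in_del]) == pytest.approx(-1.0, abs=0.1)
        assert np.mean(track.log2_ratio[in_dup]) == pytest.approx(np.log2(1.5), abs=0.1)

    def test_bins_tile_without_overlap(self):
        track = lcwgs.simulate_bins([], 50.0, seed=3)
        assert (track.bin_end - track.bin_start).eq(lcwgs.BIN_SIZE).all()
        assert (track.bin_start.to_numpy()[1:] == track.bin_end.to_numpy()[:-1]).all()

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            lcwgs.simulate_bins([], 0.0, seed=0)


class TestSegmentation:
    def test_deletion_recovered_with_published_hgvs(self):
        track = lcwgs.simulate_bins(DELETION, 100.0, seed=5)
        segments = lcwgs.segment_and_call(track)
        assert len(segments) == 1
        seg = segments[0]
        assert seg.copy_number == 1
        # boundaries within one 50 kb bin of the published coordinates
        assert abs(seg.start - 23_100_000) <= lcwgs.BIN_SIZE
        assert abs(seg.end - 28_300_000) <= lcwgs.BIN_SIZE
        assert seg.full_hgvs.startswith("NC_000015.9:g.")

    def test_idic15_two_segment_profile_recovered(self):
        track = lcwgs.simulate_bins(IDIC15, 100.0, seed=6)
        segments = lcwgs.segment_and_call(track)
        assert [s.copy_number for s in segments] == [4, 3]
        assert abs(segments[0].start - 22_550_000) <= lcwgs.BIN_SIZE
        assert abs(segments[0].end - 30_100_000) <= lcwgs.BIN_SIZE
        assert abs(segments[1].end - 32_250_000) <= lcwgs.BIN_SIZE

    def test_flat_track_has_no_segments(self):
        track = lcwgs.simulate_bins([], 100.0, seed=7)
        assert lcwgs.segment_and_call(track) == []

    def test_segmentation_is_idempotent(self):
        track = lcwgs.simulate_bins(IDIC15, 100.0, seed=8)
        segments = lcwgs.segment_and_call(track)
        rendered = lcwgs.segments_to_track(segments)
        assert lcwgs.segment_and_call(rendered) == segments

    def test_short_runs_absorbed(self):
        track = lcwgs.segments_to_track(
            [lcwgs.CnSegment(25_000_000, 25_100_000, 3)]  # 2 bins < min_bins
        )
        assert lcwgs.segment_and_call(track, min_bins=4) == []


class TestCoordinates:
    @given(
        start_bin=st.integers(0, 290),
        n_bins=st.integers(1, 9),
        copies=st.integers(0, 8).filter(lambda c: c != 2),
    )
    @settings(deadline=None, max_examples=100)
    def test_hgvs_round_trip_is_exact(self, start_bin, n_bins, copies):
        start = lcwgs.REGION[0] + start_bin * lcwgs.BIN_SIZE
        end = min(start + n_bins * lcwgs.BIN_SIZE, lcwgs.REGION[1])
        hgvs = lcwgs.to_hgvs(start, end, copies)
        rt_start, rt_end, rt_copies = lcwgs.parse_hgvs(hgvs)
        assert (rt_start, rt_end) == (start, end)
        assert rt_copies == (copies if copies > 2 else 1)

    def test_published_deletion_string(self):
        assert lcwgs.to_hgvs(23_100_000, 28_300_000, 1) == "g.23100001_28300000del"

    def test_published_duplication_strings(self):
        assert lcwgs.to_hgvs(22_550_000, 30_100_000, 4) == "g.22550001_30100000[4]"
        assert lcwgs.to_hgvs(30_300_000, 32_250_000, 3) == "g.30300001_32250000[3]"


class TestBreakpointAssignment:
    def test_type_ii_deletion_disambiguated_by_methylation_band(self):
        segments = [lcwgs.CnSegment(23_100_000, 28_300_000, 1)]
        low = lcwgs.assign_breakpoints(segments, methylation_band="low")
        high = lcwgs.assign_breakpoints(segments, methylation_band="high")
        assert low.label == "AS_del_typeII"
        assert high.label == "PWS_del_typeII"
        assert low.breakpoints == ("BP2", "BP3")

    def test_type_i_deletion(self):
        segments = [lcwgs.CnSegment(22_300_000, 28_300_000, 1)]
        call = lcwgs.assign_breakpoints(segments, methylation_band="high")
        assert call.label == "PWS_del_typeI"
        assert call.breakpoints == ("BP1", "BP3")

    def test_idic15_reports_distal_breakpoints_only(self):
        segments = [
            lcwgs.CnSegment(22_550_000, 30_100_000, 4),
            lcwgs.CnSegment(30_300_000, 32_250_000, 3),
        ]
        call = lcwgs.assign_breakpoints(segments)
        assert call.label == "idic15"
        assert call.breakpoints == ("BP4", "BP5")

    def test_interstitial_duplication(self):
        segments = [lcwgs.CnSegment(23_100_000, 28_300_000, 3)]
        assert lcwgs.assign_breakpoints(segments).label == "interstitial_dup"

    def test_no_segments_is_normal(self):
        call = lcwgs.assign_breakpoints([])
        assert call.label == "normal"
        assert call.breakpoints == ()

    def test_deletion_without_band_is_unclassified(self):
        segments = [lcwgs.CnSegment(23_100_000, 28_300_000, 1)]
        assert lcwgs.assign_breakpoints(segments).label == "unclassified"

    def test_incomplete_bp_map_rejected(self):
        with pytest.raises(ValueError, match="BP5"):
            lcwgs.assign_breakpoints([], bp_map={"BP1": 1, "BP2": 2, "BP3": 3, "BP4": 4})

    def test_unsnappable_boundary_retained_raw(self):
        segments = [lcwgs.CnSegment(24_500_000, 28_300_000, 1)]
        call = lcwgs.assign_breakpoints(segments, methylation_band="low")
        assert call.label == "unclassified"
        assert 24_500_000 in call.unsnapped


class TestSubtypeRecovery:
    PROFILES = {
        ("AS_del_typeII", "low"): [(23_100_000, 28_300_000, 1)],
        ("PWS_del_typeI", "high"): [(22_300_000, 28_300_000, 1)],
        ("idic15", None): IDIC15,
        ("interstitial_dup", None): [(23_100_000, 28_300_000, 3)],
        ("tricentric", None): [(22_550_000, 30_100_000, 7)],
    }

    def test_full_recovery_at_adequate_coverage(self):
        # 100 simulated samples per subtype at 50 reads/bin type correctly.
        rng = np.random.default_rng(77)
        for (label, band), profile in self.PROFILES.items():
            for _ in range(100):
                track = lcwgs.simulate_bins(profile, 50.0, seed=int(rng.integers(2**31)))
                segments = lcwgs.segment_and_call(track)
                call = lcwgs.assign_breakpoints(segments, methylation_band=band)
                assert call.label == label, (label, call)

    def test_low_coverage_degrades_without_crashing(self):
        # At 5 reads/bin typing is unreliable; it must still run and return
        # a structurally valid call.
        rng = np.random.default_rng(78)
        labels = set()
        for _ in range(20):
            track = lcwgs.simulate_bins(IDIC15, 5.0, seed=int(rng.integers(2**31)))
            call = lcwgs.assign_breakpoints(lcwgs.segment_and_call(track))
            labels.add(call.label)
        assert labels  # report, don't assert accuracy
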