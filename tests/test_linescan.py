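"""Line-scan extraction, normalization, alignment and distance-to-max."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spindleprofiler as sp
from spindleprofiler.core import SpindleImage


def single_channel_image(arr, px=0.1, role="motor"):
    return SpindleImage(np.asarray(arr, float)[None, :, :], (role,), px)


class TestExtractProfile:
    @pytest.mark.parametrize("width_px", [1, 3, 10])
    def test_constant_image_gives_constant_profile(self, constant_image, width_px):
        scan = sp.extract_profile(constant_image, (8.0, 2.0), (8.0, 14.0),
                                  length_um=6.5, width_px=width_px)
        for role in sp.CHANNEL_ROLES:
            assert np.allclose(scan.channel(role), 50.0)

    def test_ramp_identity_along_a_row(self):
        """On an image whose value is its column index, width-1 samples along a
        row read back the fractional column coordinate."""
        img = single_channel_image(np.tile(np.arange(50, dtype=float), (20, 1)))
        scan = sp.extract_profile(img, (1.0, 0.25), (1.0, 4.0),
                                  length_um=3.0, width_px=1)
        expected_cols = (0.25 + scan.positions_um) / img.pixel_size_um
        np.testing.assert_allclose(scan.channel("motor"), expected_cols, atol=1e-9)

    def test_width_one_on_pixel_grid_equals_direct_indexing(self, noiseless_image):
        image, _ = noiseless_image
        scan = sp.extract_profile(image, (8.0, 2.0), (8.0, 14.0),
                                  length_um=6.0, width_px=1)
        cols = np.round((2.0 + scan.positions_um) / 0.1).astype(int)
        for role in sp.CHANNEL_ROLES:
            np.testing.assert_allclose(scan.channel(role),
                                       image.channel(role)[80, cols], atol=1e-9)

    def test_argmax_matches_dense_nearest_pixel_oracle(self):
        """Brute-force oracle: nearest-pixel sampling at 0.01 µm steps."""
        spec = sp.SpindleSpec(motor_peak_offset_um=3.0, noise_model="none")
        image, _ = sp.render_spindle_image(spec)
        scan = sp.extract_profile(image, (8.0, 2.0), (8.0, 14.0),
                                  length_um=6.5, width_px=10)
        found = scan.positions_um[np.argmax(scan.channel("motor"))]

        dense_s = np.arange(0.0, 6.5, 0.01)
        rows = np.full_like(dense_s, 80)
        cols = np.round((2.0 + dense_s) / 0.1).astype(int)
        dense_vals = image.channel("motor")[rows.astype(int), cols]
        oracle = dense_s[np.argmax(dense_vals)]
        assert found == pytest.approx(3.0, abs=0.1)
        assert abs(found - oracle) <= 0.1

    def test_line_leaving_image_reports_first_bad_arclength(self, constant_image):
        with pytest.raises(ValueError, match="out-of-bounds sample at arclength"):
            sp.extract_profile(constant_image, (8.0, 12.0), (8.0, 16.0),
                               length_um=8.0, width_px=1)

    def test_zero_length_direction_rejected(self, constant_image):
        with pytest.raises(ValueError, match="zero-length"):
            sp.extract_profile(constant_image, (8.0, 2.0), (8.0, 2.0),
                               length_um=3.0, width_px=1)

    def test_width_never_shifts_argmax_beyond_one_pixel(self):
        """Perpendicular averaging of an axially symmetric band keeps the peak."""
        spec = sp.SpindleSpec(motor_peak_offset_um=3.0, noise_model="none")
        image, _ = sp.render_spindle_image(spec)
        argmaxes = []
        for width in (1, 2, 5, 10):
            scan = sp.extract_profile(image, (8.0, 2.0), (8.0, 14.0),
                                      length_um=6.5, width_px=width)
            argmaxes.append(scan.positions_um[np.argmax(scan.channel("motor"))])
        assert max(argmaxes) - min(argmaxes) <= 0.1 + 1e-9


class TestNormalize:
    def test_divides_by_channel_maximum(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2], pole=[2.0, 4.0, 8.0])
        out = sp.normalize_internal(scan)
        np.testing.assert_allclose(out.channel("pole"), [0.25, 0.5, 1.0])
        assert out.channel("pole").max() == 1.0

    def test_idempotent(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2], pole=[0.25, 0.5, 1.0])
        out = sp.normalize_internal(sp.normalize_internal(scan))
        np.testing.assert_allclose(out.channel("pole"), [0.25, 0.5, 1.0])

    @given(k=st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, k):
        scan = sp.LineScan(np.array([0.0, 0.1, 0.2, 0.3]),
                           {"a": np.array([1.0, 3.0, 2.0, 0.5]),
                            "b": k * np.array([1.0, 3.0, 2.0, 0.5])},
                           width_px=1)
        out = sp.normalize_internal(scan)
        np.testing.assert_allclose(out.channel("a"), out.channel("b"), rtol=1e-9)

    def test_all_zero_channel_names_channel(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2], motor=[0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="motor"):
            sp.normalize_internal(scan)


class TestAlignScans:
    def test_single_scan_already_at_zero_is_identity(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2, 0.3], pole=[1.0, 0.5, 0.2, 0.1],
                             motor=[0.1, 0.2, 1.0, 0.3])
        aligned = sp.align_scans([scan], reference="pole")
        assert aligned.n_scans == 1
        np.testing.assert_allclose(aligned.scans[0].positions_um, scan.positions_um)
        np.testing.assert_allclose(aligned.mean_profile["motor"], scan.channel("motor"))

    def test_shift_removal_on_preshifted_copy(self, make_linescan):
        base = make_linescan(np.arange(8) * 0.1,
                             pole=[0.1, 0.2, 1.0, 0.4, 0.3, 0.2, 0.1, 0.05],
                             motor=[0.0, 0.1, 0.2, 0.5, 1.0, 0.5, 0.2, 0.1])
        shifted = sp.LineScan(base.positions_um + 0.5, dict(base.intensities), 1)
        aligned = sp.align_scans([base, shifted], reference="pole")
        a, b = aligned.scans
        np.testing.assert_allclose(a.positions_um, b.positions_um)
        np.testing.assert_allclose(aligned.mean_profile["motor"], base.channel("motor"))

    def test_jitter_removal_against_explicit_shift_oracle(self):
        """50 scans with the reference peak jittered ±2 px align back to 0."""
        rng = np.random.default_rng(42)
        pitch = 0.1
        x = np.arange(60) * pitch
        scans, jitters = [], []
        for _ in range(50):
            j = rng.integers(-2, 3)
            jitters.append(j)
            ref = np.exp(-((x - (1.0 + j * pitch)) ** 2) / (2 * 0.3 ** 2))
            ref += rng.normal(0, 0.01, x.size)
            motor = np.exp(-((x - (4.0 + j * pitch)) ** 2) / (2 * 0.5 ** 2))
            scans.append(sp.LineScan(x, {"pole": ref, "motor": motor}, 1))
        aligned = sp.align_scans(scans, reference="pole")
        for s in aligned.scans:
            peak_pos = s.positions_um[np.argmax(s.channel("pole"))]
            assert peak_pos == pytest.approx(0.0, abs=1e-9)
        # oracle: undo each scan's known jitter by hand and compare shifts
        for s, j in zip(aligned.scans, jitters):
            assert s.meta["alignment_shift_um"] == pytest.approx(1.0 + j * pitch, abs=1e-9)

    def test_alignment_is_idempotent(self, make_linescan):
        scans = [make_linescan(np.arange(6) * 0.1 + off,
                               pole=[0.1, 1.0, 0.4, 0.3, 0.2, 0.1],
                               motor=[0.2, 0.3, 0.9, 1.0, 0.4, 0.2])
                 for off in (0.0, 0.3)]
        once = sp.align_scans(scans, reference="pole")
        twice = sp.align_scans(once.scans, reference="pole")
        np.testing.assert_allclose(once.mean_positions_um, twice.mean_positions_um)
        for role in ("pole", "motor"):
            np.testing.assert_allclose(once.mean_profile[role], twice.mean_profile[role])

    def test_low_coverage_positions_dropped(self, make_linescan):
        # two scans offset by 2 px: edges covered by only one scan vanish
        s1 = make_linescan(np.arange(6) * 0.1, pole=[0.1, 1.0, 0.4, 0.3, 0.2, 0.1])
        s2 = make_linescan(np.arange(6) * 0.1 + 0.2, pole=[0.1, 1.0, 0.4, 0.3, 0.2, 0.1])
        aligned = sp.align_scans([s1, s2], reference="pole", min_coverage=1.0)
        assert aligned.mean_positions_um.size == 6
        full = sp.align_scans([s1, s2], reference="pole", min_coverage=0.0)
        assert full.mean_positions_um.size == 6  # identical after shift removal

    def test_missing_reference_channel_rejected(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2], motor=[0.1, 1.0, 0.2])
        with pytest.raises(ValueError, match="reference channel"):
            sp.align_scans([scan], reference="pole")


class TestDistanceToMax:
    def test_motor_at_reference_peak_gives_zero(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2, 0.3], pole=[0.2, 1.0, 0.4, 0.1],
                             motor=[0.3, 1.0, 0.5, 0.2])
        aligned = sp.align_scans([scan], reference="pole")
        assert sp.distance_to_max(aligned.scans[0], "motor") == pytest.approx(0.0)

    def test_strictly_increasing_target_gives_scan_end(self, make_linescan):
        n = 66
        x = np.arange(n) * 0.1
        scan = make_linescan(x, pole=np.r_[1.0, np.full(n - 1, 0.1)],
                             motor=np.linspace(0.1, 1.0, n))
        aligned = sp.align_scans([scan], reference="pole")
        assert sp.distance_to_max(aligned.scans[0], "motor") == pytest.approx(6.5)

    def test_tie_breaks_toward_pole_and_is_recorded(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2, 0.3], pole=[1.0, 0.4, 0.3, 0.2],
                             motor=[0.2, 1.0, 1.0, 0.2])
        d = sp.distance_to_max(scan, "motor")
        assert d == pytest.approx(0.1)
        assert scan.meta["distance_to_max_tie"] is True

    def test_flat_target_channel_rejected(self, make_linescan):
        scan = make_linescan([0.0, 0.1, 0.2], pole=[1.0, 0.4, 0.2],
                             motor=[0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="flat"):
            sp.distance_to_max(scan, "motor")

    @given(k=st.floats(min_value=1e-3, max_value=1e4))
    def test_distance_is_scale_invariant(self, k):
        x = np.arange(30) * 0.1
        motor = np.exp(-((x - 1.7) ** 2) / 0.5)
        pole = np.exp(-(x ** 2) / 0.18)
        scan = sp.LineScan(x, {"pole": pole, "motor": k * motor}, 1)
        scaled = sp.normalize_internal(scan)
        aligned = sp.align_scans([scaled], reference="pole")
        assert sp.distance_to_max(aligned.scans[0], "motor") == pytest.approx(1.7)


class TestRecovery:
    def test_motor_offset_recovered_within_a_pixel(self):
        """Pipeline recovery of the simulator's motor offset at SNR ~ 10."""
        distances = []
        for seed in range(40):
            spec = sp.SpindleSpec(motor_peak_offset_um=3.5, seed=seed,
                                  channel_amplitudes={"pole": 200.0, "tubulin": 100.0,
                                                      "dna": 150.0, "motor": 110.0})
            image, _ = sp.render_spindle_image(spec)
            anchor = sp.detect_pole_anchor(image, roi=(0, 0, 160, 80))
            scan = sp.extract_profile(image, anchor, (8.0, 14.0),
                                      length_um=6.5, width_px=10)
            aligned = sp.align_scans([sp.normalize_internal(scan)], reference="pole")
            distances.append(sp.distance_to_max(aligned.scans[0], "motor"))
        assert np.mean(distances) == pytest.approx(3.5, abs=0.1)
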