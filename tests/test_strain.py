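"""Corner tracking, beat partitioning and Green-Lagrange strain estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmtquant import ImageStack, centered_roi
from cmtquant import strain, synth
from cmtquant.strain import (
    StrainConfig,
    analyze_video,
    detect_corners,
    displacement_trace,
    fit_deformation_gradient,
    green_lagrange,
    lucas_kanade,
    partition_beats,
    period_strain,
    track_points,
)
from tests.conftest import single_roi_scenario


class TestDetectCorners:
    def test_uniform_image_raises(self):
        with pytest.raises(ValueError, match="corners"):
            detect_corners(np.full((100, 100), 7.0))

    def test_band_pass_texture_is_corner_rich(self):
        tex = synth.band_pass_texture((200, 200), seed=0)
        assert len(detect_corners(tex)) >= 50

    def test_deterministic(self):
        tex = synth.band_pass_texture((120, 120), seed=1)
        np.testing.assert_array_equal(detect_corners(tex), detect_corners(tex))


class TestTracking:
    def test_static_video_tracks_in_place(self, texture_stack):
        pts = detect_corners(texture_stack[0])
        tracked = track_points(texture_stack, pts)
        err = np.linalg.norm(tracked.positions_xy[-1] - pts, axis=1)
        assert err.max() < 0.1

    def test_integer_translation_recovered(self):
        tex = synth.band_pass_texture((140, 140), seed=4)
        frames = [np.roll(tex, (0, 3 * t), axis=(0, 1)) for t in range(4)]
        stack = ImageStack(np.stack(frames), axes="t", pixel_scale_um_per_px=1.0)
        pts = detect_corners(tex[30:110, 30:110]) + 30.0
        tracked = track_points(stack, pts)
        for t in range(1, 4):
            disp = tracked.positions_xy[t] - pts
            ok = tracked.valid[t]
            np.testing.assert_allclose(disp[ok, 0], 3.0 * t, atol=0.1)
            np.testing.assert_allclose(disp[ok, 1], 0.0, atol=0.1)

    def test_affine_warp_positions_match_analytic_oracle(self):
        scn, roi = single_roi_scenario(-0.04)
        stack, truth = synth.make_deforming_video(scn, 1.0)
        rows, cols = roi.to_pixels(1.0)
        center = np.array([(cols.start + cols.stop - 1) / 2, (rows.start + rows.stop - 1) / 2])
        pts = detect_corners(np.asarray(stack[0], float)[rows, cols], max_points=100)
        pts += np.array([cols.start, rows.start])
        tracked = track_points(stack, pts)
        t_peak = int(truth["E_xx"].idxmin())
        w = truth["waveform"].iloc[t_peak]
        F = synth._deformation_gradient(-0.04 * w, 0.0, 0.0)
        expected = synth.warp_points(pts, F, center)
        ok = tracked.valid[t_peak]
        err = np.linalg.norm(tracked.positions_xy[t_peak][ok] - expected[ok], axis=1)
        assert np.median(err) < 0.2

    def test_all_points_lost_raises(self):
        # frames of pure noise share no trackable structure with frame 0
        rng = np.random.default_rng(0)
        frames = np.stack([rng.random((80, 80)) * 255 for _ in range(3)])
        stack = ImageStack(frames, axes="t", pixel_scale_um_per_px=1.0)
        pts = np.array([[40.0, 40.0], [30.0, 50.0], [50.0, 30.0], [45.0, 45.0]])
        with pytest.raises(ValueError, match="lost"):
            track_points(stack, pts)


class TestPartitionBeats:
    def test_halfway_reference_frames(self):
        trace = np.zeros(40)
        trace[[10, 20, 30]] = 1.0
        part = partition_beats(trace)
        np.testing.assert_array_equal(part.peak_frames, [10, 20, 30])
        np.testing.assert_array_equal(part.reference_frames, [15, 25])
        assert part.periods == [(15, 25)]

    @pytest.mark.parametrize("n_peaks", range(3, 11))
    def test_count_law_periods_equal_peaks_minus_two(self, n_peaks):
        w = synth.beat_waveform(n_peaks * 20 + 10, 20, duty=0.6)
        part = partition_beats(w)
        assert len(part.peak_frames) == n_peaks
        assert part.n_periods == n_peaks - 2
        assert len(part.reference_frames) == n_peaks - 1

    def test_flat_trace_has_no_periods(self):
        part = partition_beats(np.full(30, 2.0))
        assert part.n_periods == 0 and len(part.peak_frames) == 0

    def test_fewer_than_three_peaks_reports_zero_periods(self):
        w = synth.beat_waveform(45, 20, duty=0.6)  # two pulses only
        part = partition_beats(w)
        assert part.n_periods == 0


class TestDeformationGradient:
    def test_pure_translation_gives_identity(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        np.testing.assert_allclose(fit_deformation_gradient(X, X + [3.0, -2.0]), np.eye(2), atol=1e-12)

    def test_exact_affine_recovered_to_machine_precision(self):
        F0 = np.array([[0.99, 0.0], [0.0, 1.00]])
        rng = np.random.default_rng(5)
        X = rng.random((12, 2)) * 50
        x = X @ F0.T + [4.0, 7.0]
        np.testing.assert_allclose(fit_deformation_gradient(X, x), F0, atol=1e-12)

    def test_two_points_underdetermined(self):
        with pytest.raises(ValueError):
            fit_deformation_gradient(np.array([[0.0, 0], [1, 1]]), np.array([[0.0, 0], [1, 1]]))

    def test_collinear_points_rejected(self):
        X = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(ValueError, match="collinear"):
            fit_deformation_gradient(X, X)


class TestGreenLagrange:
    def test_identity_gives_zero_strain(self):
        np.testing.assert_array_equal(green_lagrange(np.eye(2)), np.zeros((2, 2)))

    def test_uniaxial_stretch_closed_form(self):
        E = green_lagrange(np.diag([1.1, 1.0]))
        assert E[0, 0] == pytest.approx(0.105)
        assert E[1, 1] == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-np.pi, np.pi))
    def test_rotation_invariance(self, theta):
        c, s = np.cos(theta), np.sin(theta)
        E = green_lagrange(np.array([[c, -s], [s, c]]))
        assert np.abs(E).max() < 1e-12

    def test_symmetry_exact(self):
        F = np.array([[1.02, 0.01], [-0.03, 0.98]])
        E = green_lagrange(F)
        assert E[0, 1] == E[1, 0]


class TestPeriodStrain:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([0, -0.01, -0.02, -0.01], -0.02),
            ([0, 0.006, 0.002], 0.006),  # passive stretch of an injured centre
            ([0, 0.01, -0.02], -0.02),  # larger magnitude wins, sign preserved
        ],
    )
    def test_signed_max_magnitude(self, series, expected):
        assert period_strain(np.array(series)) == pytest.approx(expected)


class TestAnalyzeVideo:
    def test_static_video_reports_no_beats(self, texture_stack):
        roi = centered_roi((120, 120), (80.0, 80.0), 1.0)
        result = analyze_video(texture_stack, {"center": roi})
        assert result.no_beats and result.mean_E_xx == {}

    def test_prescribed_contractile_strain_recovered(self):
        scn, roi = single_roi_scenario(-0.014)
        stack, _ = synth.make_deforming_video(scn, 1.0)
        result = analyze_video(stack, {"center": roi})
        assert result.mean_E_xx["center"] == pytest.approx(-0.014, abs=0.002)

    def test_period_strain_tensors_consistent(self):
        # stored E must equal (F^T F - I)/2 of its own F: check symmetry and
        # first-frame zeros on a real analysis
        scn, roi = single_roi_scenario(-0.03)
        stack, _ = synth.make_deforming_video(scn, 1.0)
        result = analyze_video(stack, {"center": roi})
        for p in result.per_period:
            assert p.E_xx_series[0] == 0.0
            for E in p.E_series:
                assert E[0, 1] == E[1, 0]

    def test_injured_center_and_contractile_adjacent_signs(self):
        center = synth.ROIDeformation(
            roi=synth.ROISpec((15.0, 30.0), (100.0, 100.0), "center"), peak_E_xx=0.006
        )
        adjacent = synth.ROIDeformation(
            roi=synth.ROISpec((195.0, 30.0), (100.0, 100.0), "adjacent"), peak_E_xx=-0.028
        )
        scn = synth.DeformationScenario(
            base_texture_seed=9, n_frames=60, beat_period_frames=20,
            rois=(center, adjacent), image_shape_px=(160, 310),
        )
        stack, _ = synth.make_deforming_video(scn, 1.0)
        result = analyze_video(stack, {"center": center.roi, "adjacent": adjacent.roi})
        assert result.mean_E_xx["center"] > 0
        assert result.mean_E_xx["adjacent"] < 0
        assert result.mean_E_xx["adjacent"] == pytest.approx(-0.028, abs=0.002)
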