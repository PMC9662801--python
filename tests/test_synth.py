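"""Synthetic-data generators: determinism and analytic ground truth."""

import numpy as np
import pytest

from cmtquant import centered_roi
from cmtquant import synth
from cmtquant.synth import (
    Bar,
    DeformationScenario,
    FibrilScenario,
    ROIDeformation,
    TwitchScenario,
    beat_waveform,
    make_calcium_trace,
    make_deforming_video,
    make_fibril_stack,
    make_hertz_curve,
    make_pillar_video,
)
from tests.conftest import single_roi_scenario


class TestWaveform:
    def test_zero_outside_pulses_and_unit_peak(self):
        w = beat_waveform(80, 40, duty=0.6)
        assert w[0] == 0 and w[40] == 0  # period boundaries are diastolic
        assert w.max() == pytest.approx(1.0)
        assert (w >= 0).all() and (w <= 1).all()

    def test_one_pulse_per_period(self):
        w = beat_waveform(120, 40, duty=0.5)
        assert w[20] == pytest.approx(1.0) and w[60] == pytest.approx(1.0)


class TestDeformingVideo:
    def test_zero_strain_gives_static_video(self):
        scn, _ = single_roi_scenario(0.0)
        stack, truth = make_deforming_video(scn, 1.0)
        for t in range(1, stack.n_planes):
            np.testing.assert_allclose(stack[t], stack[0], atol=1e-9)
        assert (truth["E_xx"] == 0).all()

    def test_peak_stretch_matches_closed_form(self):
        # lambda = sqrt(1 + 2 E) for a uniaxial Green-Lagrange strain
        scn, _ = single_roi_scenario(-0.02)
        _, truth = make_deforming_video(scn, 1.0)
        peak = truth["E_xx"].min()
        assert peak == pytest.approx(-0.02)
        lam = np.sqrt(1 + 2 * peak)
        assert lam == pytest.approx(np.sqrt(0.96))

    def test_warped_corner_points_reproduce_prescribed_F(self):
        # sampling a warped frame at analytically warped positions must
        # return the base texture values at the original positions
        from scipy import ndimage

        scn, roi = single_roi_scenario(-0.04, peak_E_yy=0.01)
        stack, truth = make_deforming_video(scn, 1.0)
        t_peak = int(truth["E_xx"].idxmin())
        w = truth["waveform"].iloc[t_peak]
        F = synth._deformation_gradient(-0.04 * w, 0.01 * w, 0.0)
        rows, cols = roi.to_pixels(1.0)
        center = np.array([(cols.start + cols.stop - 1) / 2, (rows.start + rows.stop - 1) / 2])
        square = center + np.array([[-20, -20], [20, -20], [20, 20], [-20, 20]], float)
        warped = synth.warp_points(square, F, center)
        tex = synth.band_pass_texture((160, 160), scn.base_texture_seed)
        ref_vals = ndimage.map_coordinates(tex, [square[:, 1], square[:, 0]], order=1)
        cur_vals = ndimage.map_coordinates(
            np.asarray(stack[t_peak], float), [warped[:, 1], warped[:, 0]], order=1
        )
        np.testing.assert_allclose(cur_vals, ref_vals, atol=1.0)  # interp tolerance, 0..255 range

    def test_deterministic_given_seed(self):
        scn, _ = single_roi_scenario(-0.02)
        s1, _ = make_deforming_video(scn, 1.0)
        s2, _ = make_deforming_video(scn, 1.0)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)

    def test_excessive_strain_rejected(self):
        with pytest.raises(ValueError):
            ROIDeformation(roi=centered_roi((160, 160), (100, 100), 1.0), peak_E_xx=0.25)


class TestPillarVideo:
    def test_zero_deflection_gives_static_video(self):
        scn = TwitchScenario(peak_deflection_um=0.0, n_frames=20, beat_period_frames=10)
        stack, truth = make_pillar_video(scn, 2.68, 0.5)
        np.testing.assert_array_equal(stack[5], stack[0])
        assert (truth["force_uN"] == 0).all()

    def test_peak_force_is_spring_constant_times_deflection(self):
        scn = TwitchScenario(peak_deflection_um=1.0, n_frames=60, beat_period_frames=60)
        _, truth = make_pillar_video(scn, 2.68, 0.5)
        assert truth["force_uN"].max() == pytest.approx(2.68)

    def test_cap_center_of_mass_matches_analytic_center(self):
        scn = TwitchScenario(peak_deflection_um=1.5, n_frames=30, beat_period_frames=30, noise_sd=0.0)
        stack, truth = make_pillar_video(scn, 2.68, 0.5)
        for t in [0, 10, 15]:
            img = 200.0 - np.asarray(stack[t], float)  # cap mass is dark
            cx_true = truth["x_left_px"].iloc[t]
            win = img[:, : stack.plane_shape[1] // 2]
            yy, xx = np.mgrid[0 : win.shape[0], 0 : win.shape[1]]
            cx = (win * xx).sum() / win.sum()
            assert abs(cx - cx_true) < 0.05

    def test_deflection_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="out of frame"):
            scn = TwitchScenario(peak_deflection_um=100.0, n_frames=20, beat_period_frames=10)
            make_pillar_video(scn, 2.68, 0.5)


class TestFibrilStack:
    def test_no_bars_gives_zero_truth(self):
        stack, truth = make_fibril_stack(FibrilScenario(bars=()))
        assert truth == 0.0
        assert stack.n_planes == 3

    def test_truth_excludes_short_bars(self):
        bars = (Bar((40.0, 40.0), 0.0, 10.0), Bar((40.0, 80.0), 0.0, 5.0))
        _, truth = make_fibril_stack(FibrilScenario(bars=bars))
        assert truth == pytest.approx(10.0)

    def test_truth_is_filtered_sum_by_construction(self):
        lengths = [4.0, 7.5, 6.0, 12.0]
        bars = tuple(Bar((30.0, 20.0 + 25.0 * i), 0.0, L) for i, L in enumerate(lengths))
        _, truth = make_fibril_stack(FibrilScenario(bars=bars))
        assert truth == pytest.approx(sum(L for L in lengths if L > 6.0))

    def test_overlapping_bars_rejected(self):
        bars = (Bar((40.0, 40.0), 0.0, 10.0), Bar((42.0, 40.0), 0.1, 10.0))
        with pytest.raises(ValueError, match="overlap"):
            make_fibril_stack(FibrilScenario(bars=bars))

    def test_bar_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_fibril_stack(FibrilScenario(bars=(Bar((1.0, 1.0), 0.0, 20.0),)))


class TestCalciumTrace:
    def test_zero_amplitude_flat_trace(self):
        trace, truth = make_calcium_trace(0.0, 50.0, n_beats=3, period_frames=40, noise_sd=0.0)
        np.testing.assert_allclose(trace, 50.0)
        assert truth["amplitude"] == 0.0

    def test_noiseless_peak_minus_baseline_exact_before_smoothing(self):
        trace, truth = make_calcium_trace(100.0, 20.0, n_beats=3, period_frames=60, noise_sd=0.0)
        assert trace.max() - trace.min() == pytest.approx(100.0)
        assert trace[truth["peak_frames"][0]] == pytest.approx(120.0)

    def test_monte_carlo_amplitude_recovery(self):
        # downstream check lives in the calcium tests; here only that the
        # generator's noise is unbiased around the clean pulse train
        clean, _ = make_calcium_trace(100.0, 0.0, 3, 60, noise_sd=0.0)
        noisy = np.mean(
            [make_calcium_trace(100.0, 0.0, 3, 60, noise_sd=2.0, seed=s)[0] for s in range(20)],
            axis=0,
        )
        assert np.abs(noisy - clean).mean() < 0.5

    def test_too_narrow_pulse_rejected(self):
        with pytest.raises(ValueError, match=">= 10 frames"):
            make_calcium_trace(100.0, 0.0, 3, period_frames=12, duty=0.5)


class TestHertzCurve:
    def test_zero_depth_zero_force(self):
        table = make_hertz_curve(1.5, depths_um=np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
        assert table["force_uN"].iloc[0] == 0.0

    def test_three_halves_power_law(self):
        table = make_hertz_curve(2.0, depths_um=np.array([0.5, 2.0]))
        assert table["force_uN"].iloc[1] / table["force_uN"].iloc[0] == pytest.approx(8.0)

    def test_force_matches_independent_formula_evaluation(self):
        # scalar oracle: F = 4/3 * E/(1-nu^2) * sqrt(R) * d^1.5, kPa um^2 -> uN
        table = make_hertz_curve(1.5, R_um=27.5, nu=0.5, depths_um=np.array([1.0]))
        expected = (4.0 / 3.0) * (1.5 / (1.0 - 0.25)) * np.sqrt(27.5) * 1.0**1.5 * 1e-3
        assert table["force_uN"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            make_hertz_curve(1.5, depths_um=np.array([-0.1, 1.0]))
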