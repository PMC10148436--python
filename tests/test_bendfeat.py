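"""Curvature, inflection/peak detection, error checking, bend angles."""

import numpy as np
import pytest

from wormbend.bendfeat import (
    bend_angles,
    check_feature_points,
    extract_features,
    inflection_points,
    peak_points,
    pharynx_point,
    signed_curvature,
)
from wormbend.midline import Centerline


def _line_cl(n=120, spacing=1.0):
    return Centerline(points=np.column_stack([np.arange(n) * spacing, np.zeros(n)]))


class TestPharynxPoint:
    def test_unit_spaced_120_points(self, straight_line_120):
        point, idx = pharynx_point(Centerline(points=straight_line_120))
        # L = 119 -> L/10 = 11.9 -> first cumulative arc >= 11.9 is index 12
        assert idx == 12
        assert point[0] == pytest.approx(12.0)

    def test_eleven_points(self):
        point, idx = pharynx_point(_line_cl(n=11))
        assert idx == 1

    def test_never_the_head_itself(self):
        assert pharynx_point(_line_cl(n=3, spacing=50.0))[1] > 0


class TestSignedCurvature:
    def test_collinear_points_zero(self, straight_line_120):
        assert np.allclose(signed_curvature(straight_line_120), 0.0)

    def test_circle_radius_50(self):
        th = np.linspace(0, np.pi, 60)
        pts = np.column_stack([50 * np.cos(th), 50 * np.sin(th)])
        kappa = signed_curvature(pts)
        assert np.allclose(np.abs(kappa), 0.02, rtol=0.05)

    def test_mirror_negates_curvature(self):
        rng = np.random.default_rng(4)
        s = np.linspace(0, 1, 80)
        pts = np.column_stack([100 * s, 8 * np.sin(2 * np.pi * s)])
        kappa = signed_curvature(pts)
        mirrored = pts.copy()
        mirrored[:, 0] *= -1
        assert np.allclose(signed_curvature(mirrored), -kappa)

    def test_duplicate_points_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="duplicate"):
            signed_curvature(pts)

    def test_smoothing_window_reduces_noise(self):
        rng = np.random.default_rng(5)
        s = np.linspace(0, 1, 120)
        pts = np.column_stack([120 * s, 9 * np.sin(2 * np.pi * s)])
        noisy = pts + rng.normal(0, 0.05, pts.shape)
        raw = signed_curvature(noisy)
        smooth = signed_curvature(noisy, smooth_window=7)
        assert np.abs(smooth).max() < np.abs(raw).max()


class TestInflectionPoints:
    def test_single_sign_change(self):
        assert inflection_points(np.array([0.1, 0.05, -0.05, -0.1])) == [2]

    def test_all_positive_empty(self):
        assert inflection_points(np.array([0.1, 0.2, 0.3])) == []

    def test_sinusoid_three_interior_inflections(self):
        # 1.5 wavelengths starting at an extremum: curvature crosses zero at
        # 0.25, 0.75 and 1.25 wavelengths — all interior
        s = np.linspace(0, 1.5, 300)
        pts = np.column_stack([100 * s, 10 * np.cos(2 * np.pi * s)])
        kappa = signed_curvature(pts)
        assert len(inflection_points(kappa)) == 3

    def test_zero_run_counts_once_at_midpoint(self):
        kappa = np.array([0.2, 0.1, 0.0, 0.0, 0.0, -0.1, -0.2])
        assert inflection_points(kappa) == [3]


class TestPeakPoints:
    def test_per_segment_argmax(self):
        kappa = np.array([0.1, 0.3, 0.2, -0.1, -0.4, -0.2])
        assert peak_points(kappa, [3]) == [1, 4]

    def test_straight_worm_no_peaks(self):
        assert peak_points(np.zeros(50), []) == []

    def test_tie_breaks_to_lower_index(self):
        kappa = np.array([0.1, 0.3, 0.3, 0.1])
        assert peak_points(kappa, []) == [1]

    def test_short_segments_skipped(self):
        kappa = np.array([0.5, -0.1, -0.2, -0.3, -0.2])
        # head segment has 1 point (< min_seg_pts): no peak there
        assert peak_points(kappa, [1], min_seg_pts=3) == [3]


class TestCheckFeaturePoints:
    def test_valid_alternation_unchanged(self, straight_line_120):
        c = Centerline(points=straight_line_120)
        s = np.linspace(0, 1.5, 120)
        kappa = 0.05 * np.cos(2 * np.pi * s)
        infl = inflection_points(kappa)
        peaks = peak_points(kappa, infl)
        infl2, peaks2 = check_feature_points(infl, peaks, c, kappa)
        assert infl2 == infl and peaks2 == peaks

    def test_close_inflection_pair_merged(self):
        c = _line_cl()
        kappa = 0.05 * np.ones(120)
        kappa[60] = -0.05  # single-point dip: two inflections 1 apart
        infl = inflection_points(kappa)
        assert len(infl) == 2
        infl2, peaks2 = check_feature_points(infl, peak_points(kappa, infl), c, kappa)
        assert len(infl2) <= 1
        _assert_alternation(infl2, peaks2)

    def test_weak_peaks_dropped(self):
        c = _line_cl()
        s = np.linspace(0, 1.5, 120)
        kappa = 0.05 * np.cos(2 * np.pi * s)
        kappa[100:] *= 0.001  # last lobe far below kappa_min = 0.25/119
        infl = inflection_points(kappa)
        peaks = peak_points(kappa, infl)
        infl2, peaks2 = check_feature_points(infl, peaks, c, kappa)
        assert all(abs(kappa[p]) >= 0.25 / c.L for p in peaks2)
        _assert_alternation(infl2, peaks2)


def _assert_alternation(inflections, peaks):
    for a, b in zip(inflections[:-1], inflections[1:]):
        assert sum(a <= p < b for p in peaks) == 1


class TestBendAngles:
    def test_collinear_triple_is_180(self):
        c = _line_cl(n=20)
        alphas = bend_angles([10], [5, 15], c)
        assert alphas[0] == pytest.approx(180.0)

    def test_right_angle_geometry(self):
        pts = np.array([[-5.0, 5.0], [0.0, 0.0], [5.0, 5.0]])
        c = Centerline(points=pts)
        alphas = bend_angles([1], [], c)  # flanked by head and tail
        assert alphas[0] == pytest.approx(90.0)

    def test_deeper_bend_gives_smaller_angle(self):
        def min_alpha(amplitude):
            s = np.linspace(0, 1, 120)
            pts = np.column_stack([120 * s, amplitude * np.sin(2 * np.pi * s)])
            feats = extract_features(Centerline(points=pts), smooth_window=0)
            return feats.max_amplitude_angle

        assert min_alpha(16.0) < min_alpha(8.0)


class TestExtractFeatures:
    def test_alternation_invariant_on_video(self, short_video):
        from wormbend.bendcount import run_counter_on_video

        params, frames, _ = short_video
        _, _, records = run_counter_on_video(frames, params.fps)
        checked = 0
        for rec in records:
            if rec.features is None:
                continue
            _assert_alternation(rec.features.inflections, rec.features.peaks)
            checked += 1
        assert checked > 100

    def test_reflection_preserves_features(self):
        s = np.linspace(0, 1, 120)
        pts = np.column_stack([120 * s, 9 * np.sin(2 * np.pi * s)])
        f1 = extract_features(Centerline(points=pts), smooth_window=0)
        mirrored = pts * np.array([1.0, -1.0])
        f2 = extract_features(Centerline(points=mirrored), smooth_window=0)
        assert np.allclose(f1.kappa, -f2.kappa)
        assert f1.inflections == f2.inflections
        assert f1.peaks == f2.peaks
        assert np.allclose(f1.alphas, f2.alphas)

    def test_peak_positions_match_analytic_extrema(self):
        # sine midline: curvature extrema sit at the lateral extrema
        s = np.linspace(0, 1, 240)
        pts = np.column_stack([240 * s, 19.2 * np.sin(2 * np.pi * s)])
        feats = extract_features(Centerline(points=pts), smooth_window=0)
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        L = arc[-1]
        analytic = [0.25, 0.75]  # fractions of the x span where |y| peaks
        got = sorted(arc[p] / L for p in feats.peaks if 10 < p < 230)
        assert len(got) == 2
        for g, a in zip(got, analytic):
            assert abs(g - a) < 0.03
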