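"""DSNT math, PCK, classical head/tail identification, and tracking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormbend.keypoints import (
    EndpointsNotFound,
    HeadTailPair,
    dsnt_coordinates,
    dsnt_loss,
    endpoints_by_curvature,
    gaussian_target,
    head_by_grayscale,
    norm_to_pixel,
    normalize_heatmap,
    pck,
    resolve_first_frame,
    track_head_tail,
)


class TestNormalizeHeatmap:
    def test_equal_logits_give_uniform(self):
        m = normalize_heatmap(np.zeros((5, 5)))
        assert np.allclose(m.probs, 1.0 / 25.0)

    def test_sums_to_one_for_random_input(self):
        rng = np.random.default_rng(1)
        m = normalize_heatmap(rng.normal(size=(7, 3)))
        assert m.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (m.probs >= 0).all()

    def test_saturation_at_large_logit(self):
        h = np.zeros((5, 5))
        h[2, 3] = 50.0
        m = normalize_heatmap(h)
        assert m.probs[2, 3] > 1.0 - 1e-9

    def test_coordinate_matrix_convention(self):
        m = normalize_heatmap(np.zeros((5, 5)))
        # 1-based cell j: x_j = (2j - W - 1)/W
        assert np.allclose(m.X[0], [(2 * j - 6) / 5 for j in range(1, 6)])
        assert np.allclose(m.Y[:, 0], [(2 * i - 6) / 5 for i in range(1, 6)])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_heatmap(np.array([[np.inf, 0.0]]))


class TestDsntCoordinates:
    def test_uniform_heatmap_gives_center(self):
        assert dsnt_coordinates(normalize_heatmap(np.zeros((5, 5)))) == (0.0, 0.0)

    def test_one_hot_top_left(self):
        h = np.full((5, 5), -1e3)
        h[0, 0] = 1e3
        x, y = dsnt_coordinates(normalize_heatmap(h))
        assert (x, y) == pytest.approx((-0.8, -0.8))

    def test_one_hot_center(self):
        h = np.full((5, 5), -1e3)
        h[2, 2] = 1e3
        assert dsnt_coordinates(normalize_heatmap(h)) == pytest.approx((0.0, 0.0))

    def test_coordinates_strictly_inside_unit_box(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = normalize_heatmap(rng.normal(scale=5.0, size=(5, 5)))
            x, y = dsnt_coordinates(m)
            assert -1.0 < x < 1.0 and -1.0 < y < 1.0

    def test_pixel_mapping_roundtrip(self):
        # normalized center of a 5x5 cell grid on a 100x100 image -> center px
        x, y = norm_to_pixel((0.0, 0.0), (100, 100))
        assert (x, y) == pytest.approx((49.5, 49.5))


class TestDsntLoss:
    def test_zero_at_perfect_prediction_no_regularizer(self):
        h = np.zeros((5, 5))
        assert dsnt_loss(normalize_heatmap(h), p=(0.0, 0.0), lam=0.0) == 0.0

    def test_euclidean_norm_value(self):
        m = normalize_heatmap(np.zeros((5, 5)))  # mu = (0, 0)
        assert dsnt_loss(m, p=(0.3, 0.4), lam=0.0) == pytest.approx(0.5)

    def test_js_term_zero_for_matching_target(self):
        g = gaussian_target((0.0, 0.0), (5, 5), sigma_cells=1.0)
        # heatmap whose softmax equals the gaussian target exactly
        m = normalize_heatmap(np.log(g))
        assert dsnt_loss(m, p=(0.0, 0.0), lam=1.0) == pytest.approx(0.0, abs=1e-9)

    def test_loss_nonnegative_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = normalize_heatmap(rng.normal(size=(5, 5)))
            p = tuple(rng.uniform(-0.9, 0.9, 2))
            assert dsnt_loss(m, p=p, lam=rng.uniform(0, 2)) >= 0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            dsnt_loss(normalize_heatmap(np.zeros((5, 5))), p=(0, 0), lam=-0.1)


class TestPck:
    def test_perfect_predictions(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert pck(pts, pts) == 1.0

    def test_one_of_two_outside_radius(self):
        truth = np.array([[0.0, 0.0], [50.0, 50.0]])
        pred = truth + np.array([[0.0, 0.0], [10.0, 0.0]])
        assert pck(pred, truth, n_pixels=8) == 0.5

    def test_boundary_is_inclusive(self):
        truth = np.array([[0.0, 0.0], [10.0, 10.0]])
        pred = truth + np.array([[8.0, 0.0], [0.0, 8.0]])
        assert pck(pred, truth, n_pixels=8) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pck(np.zeros((2, 2)), np.zeros((3, 2)))


def _ellipse(a, b, n=400):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([100 + a * np.cos(th), 100 + b * np.sin(th)])


class TestEndpointsByCurvature:
    def test_ellipse_major_axis_extremes(self):
        end_a, end_b, _ = endpoints_by_curvature(_ellipse(80, 20))
        found = sorted([tuple(end_a), tuple(end_b)])
        expected = sorted([(20.0, 100.0), (180.0, 100.0)])
        for f, e in zip(found, expected):
            assert np.linalg.norm(np.array(f) - np.array(e)) < 3.0

    def test_circle_has_no_sharp_points(self):
        with pytest.raises(EndpointsNotFound):
            endpoints_by_curvature(_ellipse(50, 50))

    def test_sharper_taper_is_tail_guess(self, short_video):
        from wormbend.segment import segment_frame

        params, frames, gt = short_video
        wm = segment_frame(frames[0])
        _, _, tail_guess = endpoints_by_curvature(wm.boundary)
        assert np.linalg.norm(tail_guess - gt.tails[0]) < 8.0


class TestHeadByGrayscale:
    def _frame_with_bright_a(self):
        frame = np.full((50, 90), 200, np.uint8)
        frame[20:30, 5:25] = 90    # end A region, brighter worm
        frame[20:30, 60:80] = 60   # end B region
        return frame, np.array([15.0, 25.0]), np.array([70.0, 25.0])

    def test_brighter_end_is_head(self):
        frame, a, b = self._frame_with_bright_a()
        assert head_by_grayscale(frame, a, b, radius_px=4) == "A"

    def test_equal_brightness_is_ambiguous(self):
        frame = np.full((50, 90), 60, np.uint8)
        a, b = np.array([15.0, 25.0]), np.array([70.0, 25.0])
        assert head_by_grayscale(frame, a, b) is None

    def test_polarity_flag_inverts(self):
        frame, a, b = self._frame_with_bright_a()
        assert head_by_grayscale(frame, a, b, radius_px=4, brighter_is_head=False) == "B"


class TestResolveFirstFrame:
    A, B = np.array([0.0, 0.0]), np.array([100.0, 0.0])

    def test_agreement_no_conflict(self):
        pair = resolve_first_frame(self.A, self.B, "A", "A")
        assert np.allclose(pair.head, self.A) and not pair.conflict

    def test_disagreement_with_override(self):
        pair = resolve_first_frame(self.A, self.B, "A", "B", assume_head="brighter")
        assert np.allclose(pair.head, self.B) and pair.conflict

    def test_disagreement_without_override_raises(self):
        with pytest.raises(RuntimeError, match="conflict"):
            resolve_first_frame(self.A, self.B, "A", "B")

    def test_ambiguous_grayscale_falls_back_to_curvature(self):
        pair = resolve_first_frame(self.A, self.B, "B", None)
        assert np.allclose(pair.head, self.B) and pair.conflict


class TestTrackHeadTail:
    def test_minimal_motion_assignment(self):
        prev = HeadTailPair(head=(0.0, 0.0), tail=(100.0, 0.0), source="manual")
        pair = track_head_tail(prev, (np.array([2.0, 0.0]), np.array([98.0, 0.0])))
        assert np.allclose(pair.head, [2.0, 0.0])

    def test_candidate_order_irrelevant(self):
        prev = HeadTailPair(head=(0.0, 0.0), tail=(100.0, 0.0), source="manual")
        pair = track_head_tail(prev, (np.array([98.0, 0.0]), np.array([2.0, 0.0])))
        assert np.allclose(pair.head, [2.0, 0.0])

    @given(
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
    )
    @settings(max_examples=30, deadline=None)
    def test_translation_symmetry(self, dx, dy):
        shift = np.array([dx, dy])
        prev = HeadTailPair(head=(0.0, 0.0), tail=(100.0, 0.0), source="manual")
        prev_s = HeadTailPair(head=shift, tail=shift + [100.0, 0.0], source="manual")
        cands = (np.array([5.0, 3.0]), np.array([95.0, -2.0]))
        p1 = track_head_tail(prev, cands)
        p2 = track_head_tail(prev_s, tuple(c + shift for c in cands))
        assert np.allclose(p2.head - shift, p1.head, atol=1e-6)
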