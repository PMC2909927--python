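"""Boundary detection: integrodifferential operator, Canny + circular Hough,
blob estimate, and the three full segmentations, checked against ground truth
and independent brute-force oracles."""

import math

import numpy as np
import pytest
from skimage.draw import circle_perimeter

from irispipe.config import PipelineConfig
from irispipe.errors import (DegenerateInputError, EstimateFailureError,
                             InvalidArgumentError, SegmentationFailureError)
from irispipe.evaluation import boundary_displacements
from irispipe.segmentation import (SearchSpec, canny_edge_map, circular_hough,
                                   integrodifferential_search, segment_daugman,
                                   segment_masek, segment_proposed,
                                   threshold_pupil_estimate)

from conftest import make_eye
from oracles import brute_force_integrodiff, naive_contour_mean


def dark_disk(size=160, center=(100, 100), radius=30, fg=0.1, bg=0.9):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.full((size, size), bg)
    img[np.hypot(yy - center[0], xx - center[1]) <= radius] = fg
    return img


class TestIntegrodifferential:
    def test_dark_disk_full_grid(self):
        # dark disk on bright background: pupil-like, outward derivative
        # positive at the boundary
        img = dark_disk()
        circle, score = integrodifferential_search(
            img, SearchSpec(None, (20, 40), 1.0, 64))
        assert abs(circle.row - 100) <= 1 and abs(circle.col - 100) <= 1
        assert abs(circle.radius - 30) <= 1
        assert score > 0

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            integrodifferential_search(np.full((80, 80), 0.5),
                                       SearchSpec(None, (10, 20), 1.0, 32))

    def test_single_center_radius_profile_matches_1d_oracle(self):
        img = dark_disk()
        spec = SearchSpec(np.array([[100, 100]]), (25, 35), 1.0, 64)
        circle, _ = integrodifferential_search(img, spec)
        assert abs(circle.radius - 30) <= 1
        thetas = [2 * math.pi * a / 64 for a in range(64)]
        from scipy.ndimage import gaussian_filter1d
        means = [naive_contour_mean(img, 100, 100, r, thetas)
                 for r in range(25, 37)]
        deriv = np.diff(means)
        best = np.arange(25, 36)[np.argmax(
            gaussian_filter1d(deriv, 1.0, mode="nearest"))]
        assert circle.radius == best

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SearchSpec(np.empty((0, 2)), (5, 10))

    def test_matches_brute_force_on_random_instances(self):
        """Vectorized search == naive enumeration (argmax identity) on
        randomized toy images, full candidate grid."""
        rng = np.random.default_rng(11)
        for _ in range(3):
            H = W = 36
            img = rng.uniform(0.3, 0.7, (H, W))
            cy, cx = rng.integers(13, 23, size=2)
            r = rng.integers(6, 10)
            yy, xx = np.mgrid[0:H, 0:W]
            img[np.hypot(yy - cy, xx - cx) <= r] *= 0.25
            circle, score = integrodifferential_search(
                img, SearchSpec(None, (5, 11), 1.0, 32))
            centers = [(y, x) for y in range(H) for x in range(W)]
            (oy, ox, orad), oscore = brute_force_integrodiff(
                img, centers, (5, 11), 1.0, 32)
            assert (circle.row, circle.col, circle.radius) == (oy, ox, orad)
            assert score == pytest.approx(oscore, rel=1e-9)


class TestCanny:
    def test_step_edge_found_at_step_column(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        edges = canny_edge_map(img, sigma=2.0)
        cols = np.nonzero(edges)[1]
        assert len(cols) > 0
        assert np.all(np.abs(cols - 31.5) <= 1.5)

    def test_constant_image_no_edges(self):
        assert not canny_edge_map(np.full((64, 64), 0.3)).any()

    def test_disk_edges_on_the_circle(self):
        img = dark_disk(size=120, center=(60, 60), radius=25)
        edges = canny_edge_map(img, sigma=2.0)
        ys, xs = np.nonzero(edges)
        d = np.hypot(ys - 60, xs - 60)
        assert len(d) > 50
        assert np.all(np.abs(d - 25) <= 1.5)

    def test_threshold_order_enforced(self):
        with pytest.raises(InvalidArgumentError):
            canny_edge_map(np.zeros((64, 64)), 2.0, 0.5, 0.2)


class TestHough:
    def test_perfect_circle_recovered_exactly(self):
        edges = np.zeros((100, 100), dtype=bool)
        rr, cc = circle_perimeter(50, 50, 20)
        edges[rr, cc] = True
        n_edge = int(edges.sum())
        circle, votes = circular_hough(edges, (15, 25))
        assert (circle.row, circle.col, circle.radius) == (50.0, 50.0, 20.0)
        assert votes == n_edge

    def test_single_edge_pixel(self):
        edges = np.zeros((60, 60), dtype=bool)
        edges[30, 30] = True
        circle, votes = circular_hough(edges, (5, 10))
        assert votes == 1
        assert circle.radius == 5  # tie-break: smallest radius first
        d = math.hypot(circle.row - 30, circle.col - 30)
        assert abs(d - circle.radius) <= 0.75  # rasterized circle of centres

    def test_denser_circle_wins(self):
        edges = np.zeros((120, 120), dtype=bool)
        rr, cc = circle_perimeter(60, 60, 30)
        edges[rr, cc] = True          # full outer circle
        rr, cc = circle_perimeter(60, 60, 15)
        edges[rr[::2], cc[::2]] = True  # half-sampled inner circle
        circle, _ = circular_hough(edges, (10, 35))
        assert circle.radius == 30

    def test_empty_edge_map_rejected(self):
        with pytest.raises(InvalidArgumentError):
            circular_hough(np.zeros((50, 50), dtype=bool), (5, 10))


class TestBlobEstimate:
    def test_clean_disk_centroid_and_area(self):
        img = dark_disk(size=200, center=(100, 100), radius=40)
        circle, area = threshold_pupil_estimate(img)
        assert math.hypot(circle.row - 100, circle.col - 100) <= 0.5
        assert area == pytest.approx(math.pi * 40 ** 2, rel=0.02)

    def test_corner_blob_ignored(self):
        img = dark_disk(size=200, center=(100, 100), radius=30)
        img[:70, :70] = 0.1  # large dark corner patch, centroid off-center
        circle, _ = threshold_pupil_estimate(img)
        assert math.hypot(circle.row - 100, circle.col - 100) <= 1.0

    def test_all_bright_image_fails(self):
        with pytest.raises(EstimateFailureError):
            threshold_pupil_estimate(np.full((100, 100), 0.9))


class TestFullSegmentations:
    @pytest.mark.parametrize("segment", [segment_daugman, segment_masek,
                                         segment_proposed])
    def test_clean_eye_both_boundaries_within_2px(self, texture, segment):
        _, img, truth = make_eye(texture, noise_sd=0.0, pupil_offset=(0.0, 0.0))
        res = segment(img)
        p, l = boundary_displacements(res, truth)
        assert p <= 2.0 and l <= 2.0

    @pytest.mark.parametrize("segment", [segment_daugman, segment_masek,
                                         segment_proposed])
    def test_containment_invariant(self, texture, segment):
        _, img, _ = make_eye(texture)
        res = segment(img)
        assert res.containment_slack() >= -1.0

    def test_flat_image_fails_at_limbal_stage(self):
        with pytest.raises(SegmentationFailureError) as exc:
            segment_daugman(np.full((128, 128), 0.5))
        assert exc.value.stage == "limbal"

    def test_masek_edge_free_image_fails_at_limbal_stage(self):
        with pytest.raises(SegmentationFailureError) as exc:
            segment_masek(np.full((128, 128), 0.5))
        assert exc.value.stage == "limbal"

    def test_proposed_nonconcentric_recovers_both_centers(self, texture):
        """Pupil offset 5 px from the limbal center: the two detected centers
        must differ and each boundary must be accurate."""
        _, img, truth = make_eye(texture, pupil_offset=(3.0, 4.0), noise_sd=0.0)
        res = segment_proposed(img)
        p, l = boundary_displacements(res, truth)
        assert p <= 1.0
        assert l <= 2.0
        assert (res.pupil.row, res.pupil.col) != (res.limbal.row, res.limbal.col)

    def test_proposed_pupil_stage_evaluates_exactly_100_candidates(self, noisy_eye):
        _, img, _ = noisy_eye
        res = segment_proposed(img)
        assert res.details["n_pupil_candidates"] == 100

    def test_proposed_total_candidates_bounded(self, noisy_eye):
        _, img, _ = noisy_eye
        res = segment_proposed(img)
        total = (res.details["n_pupil_candidates"]
                 + res.details["n_limbal_candidates"])
        assert total <= 200

    def test_daugman_limbal_stage_is_exhaustive(self, texture):
        _, img, _ = make_eye(texture, noise_sd=0.0, pupil_offset=(0.0, 0.0))
        res = segment_daugman(img)
        assert res.details["n_limbal_candidates"] == img.size

    def test_all_bright_image_fails_at_estimate_stage(self):
        with pytest.raises(SegmentationFailureError) as exc:
            segment_proposed(np.full((128, 128), 0.9))
        assert exc.value.stage == "estimate"

    def test_shift_equivariance(self, texture):
        """Translating the eye translates every detected circle with it."""
        _, img, truth = make_eye(texture, noise_sd=0.0, size=150,
                                 limbal_radius=55.0)
        dr, dc = 4, 6
        shifted = np.pad(img, ((dr, 0), (dc, 0)), mode="edge")[:150, :150]
        a = segment_proposed(img)
        b = segment_proposed(shifted)
        assert abs(b.pupil.row - a.pupil.row - dr) <= 1
        assert abs(b.pupil.col - a.pupil.col - dc) <= 1
        assert abs(b.limbal.row - a.limbal.row - dr) <= 1
        assert abs(b.limbal.col - a.limbal.col - dc) <= 1

    def test_small_image_rejected(self):
        with pytest.raises(InvalidArgumentError):
            segment_proposed(np.zeros((32, 32)))
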