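"""Synthetic eye generator: determinism, ground-truth exactness, consistency
with the rubber-sheet geometry."""

import numpy as np
import pytest

from irispipe.errors import InvalidArgumentError
from irispipe.normalization import rubber_sheet
from irispipe.synthetic import (EyeSpec, generate_dilation_series,
                                generate_iris_texture, render_eye)
from irispipe.types import SegmentationResult

from conftest import make_eye


class TestTexture:
    def test_same_seed_bitwise_identical(self):
        a = generate_iris_texture(7, 20, 240)
        b = generate_iris_texture(7, 20, 240)
        assert np.array_equal(a.values, b.values)

    def test_distinct_seeds_differ(self):
        a = generate_iris_texture(7, 20, 240)
        b = generate_iris_texture(8, 20, 240)
        assert np.abs(a.values - b.values).mean() > 0

    def test_distinct_seeds_nearly_uncorrelated(self):
        a = generate_iris_texture(1, 20, 240).values.ravel()
        b = generate_iris_texture(2, 20, 240).values.ravel()
        # Pearson r by direct summation, independent of library helpers
        n = a.size
        sa, sb = a.sum(), b.sum()
        num = n * (a * b).sum() - sa * sb
        den = np.sqrt(n * (a * a).sum() - sa ** 2) * np.sqrt(n * (b * b).sum() - sb ** 2)
        assert abs(num / den) < 0.1

    @pytest.mark.parametrize("shape", [(0, 240), (20, 3), (-5, 240)])
    def test_bad_dimensions_rejected(self, shape):
        with pytest.raises(InvalidArgumentError):
            generate_iris_texture(1, *shape)

    def test_values_within_intensity_range(self):
        t = generate_iris_texture(3, 12, 48)
        assert t.values.min() >= 0.0 and t.values.max() <= 1.0


class TestEyeSpec:
    def test_pupil_must_fit_inside_limbal_disk(self):
        with pytest.raises(InvalidArgumentError):
            EyeSpec(height=100, width=100, pupil_center=(50, 70),
                    pupil_radius=30, limbal_center=(50, 50), limbal_radius=40)

    def test_intensity_ordering_enforced(self):
        with pytest.raises(InvalidArgumentError):
            EyeSpec(height=100, width=100, pupil_center=(50, 50),
                    pupil_radius=20, limbal_center=(50, 50), limbal_radius=40,
                    mean_intensity=(0.5, 0.4, 0.9))


class TestRender:
    def test_truth_echoes_spec_exactly(self, texture):
        spec, _, truth = make_eye(texture, pupil_radius=30.0)
        assert truth.pupil.radius == 30.0
        assert truth.pupil.center == spec.pupil_center
        assert truth.limbal.radius == spec.limbal_radius

    def test_region_intensity_ordering(self, texture):
        spec, img, truth = make_eye(texture, noise_sd=0.0,
                                    mean_intensity=(0.05, 0.5, 0.95))
        yy, xx = np.mgrid[0:spec.height, 0:spec.width].astype(float)
        d_p = np.hypot(yy - spec.pupil_center[0], xx - spec.pupil_center[1])
        d_l = np.hypot(yy - spec.limbal_center[0], xx - spec.limbal_center[1])
        pupil = img[d_p <= spec.pupil_radius - 1].mean()
        iris = img[(d_p > spec.pupil_radius + 1)
                   & (d_l <= spec.limbal_radius - 1)].mean()
        sclera = img[d_l > spec.limbal_radius + 1].mean()
        assert pupil < iris < sclera

    def test_eyelid_truth_matches_requested_coverage(self, texture):
        spec, _, truth = make_eye(texture, eyelid_coverage=0.2)
        yy, xx = np.mgrid[0:160, 0:160].astype(float)
        ann = ((np.hypot(yy - 80, xx - 80) <= 60)
               & (np.hypot(yy - spec.pupil_center[0],
                           xx - spec.pupil_center[1]) > 30))
        assert truth.occlusion_mask[ann].mean() == pytest.approx(0.2, abs=0.02)

    def test_specular_spot_recorded_in_truth(self, texture):
        _, img, truth = make_eye(texture, spots=(((80.0, 35.0), 4.0, 1.0),))
        assert truth.occlusion_mask.sum() >= np.pi * 3.5 ** 2
        assert img[truth.occlusion_mask].min() > 0.9


class TestRoundTrip:
    @pytest.mark.parametrize("pupil_radius", [20.0, 30.0, 40.0, 50.0, 60.0])
    def test_rubber_sheet_recovers_texture(self, texture, pupil_radius):
        """Noiseless render + true-circle normalization recovers the polar
        texture to within resampling error (<= 0.05 mean abs)."""
        _, img, truth = make_eye(texture, pupil_radius=pupil_radius,
                                 noise_sd=0.0, limbal_radius=70.0, size=180)
        seg = SegmentationResult(truth.pupil, truth.limbal, "truth")
        polar = rubber_sheet(img, seg, None, 20, 240)
        assert polar.valid.all()
        assert np.abs(polar.values - texture.values).mean() <= 0.05

    def test_two_dilations_same_polar_image(self, texture):
        """The same identity rendered at pupil radii 30 and 50 normalizes to
        nearly identical polar images (dilation invariance by construction)."""
        polars = []
        for r in (30.0, 50.0):
            _, img, truth = make_eye(texture, pupil_radius=r, noise_sd=0.0)
            seg = SegmentationResult(truth.pupil, truth.limbal, "truth")
            polars.append(rubber_sheet(img, seg, None, 20, 240).values)
        assert np.abs(polars[0] - polars[1]).mean() <= 0.05


class TestDilationSeries:
    def test_radii_recorded_in_truth(self, texture):
        spec, _, _ = make_eye(texture, limbal_radius=60.0)
        series = generate_dilation_series(texture, spec, [23.0, 32.0, 37.0],
                                          seed=1)
        assert [t.pupil.radius for _, t in series] == [23.0, 32.0, 37.0]

    def test_empty_radius_list(self, texture):
        spec, _, _ = make_eye(texture)
        assert generate_dilation_series(texture, spec, [], seed=1) == []

    def test_same_seed_per_item_gives_identical_images(self, texture):
        spec, _, _ = make_eye(texture)
        series = generate_dilation_series(texture, spec, [30.0, 30.0], seed=4,
                                          fresh_noise=False)
        assert np.array_equal(series[0][0], series[1][0])

    def test_fresh_noise_differs_per_item(self, texture):
        spec, _, _ = make_eye(texture)
        series = generate_dilation_series(texture, spec, [30.0, 30.0], seed=4)
        assert not np.array_equal(series[0][0], series[1][0])

    def test_radius_at_or_beyond_limbus_rejected(self, texture):
        spec, _, _ = make_eye(texture, limbal_radius=60.0)
        with pytest.raises(InvalidArgumentError):
            generate_dilation_series(texture, spec, [60.0], seed=1)
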