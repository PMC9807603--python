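"""Pre-processing: gamma loop against a scalar oracle, box detection on
phantoms with known geometry, crop/rescale arithmetic and the composed
pipeline's standardisation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastoseg.phantom import PhantomSpec, generate_phantom
from blastoseg.preprocess import (BoundingBox, Micrograph, crop,
                                  detect_bounding_box, gamma_correct,
                                  minmax_normalize, preprocess_mask,
                                  preprocess_pipeline, rescale_to_physical)


def gamma_loop_oracle(median0: float, max_steps: int = 3):
    """Scalar brute-force iteration of gamma = 1.25*m + 0.375 for a constant
    image, whose median equals its value."""
    m = median0
    gammas = []
    while not (0.45 <= m <= 0.75) and len(gammas) < max_steps:
        g = 1.25 * m + 0.375
        m = m ** g
        gammas.append(g)
    return m, gammas


class TestGammaLoop:
    def test_median_in_band_is_untouched(self):
        res = gamma_correct(np.full((16, 16), 0.6))
        assert res.n_transforms == 0
        assert np.array_equal(res.image, np.full((16, 16), 0.6))

    @pytest.mark.parametrize("value", [0.05, 0.1, 0.2, 0.3, 0.44, 0.76, 0.9, 0.99])
    def test_matches_scalar_oracle_on_constant_images(self, value):
        res = gamma_correct(np.full((20, 20), value))
        median, gammas = gamma_loop_oracle(value)
        assert res.n_transforms == len(gammas)
        assert res.gammas_applied == pytest.approx(gammas, abs=1e-9)
        assert res.final_median == pytest.approx(median, abs=1e-9)

    def test_dark_constant_exhausts_three_transforms(self):
        res = gamma_correct(np.zeros((8, 8)))
        assert res.n_transforms == 3
        assert res.final_median == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gamma_correct(np.full((4, 4), 1.5))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4,
                    max_size=64))
    @settings(max_examples=50, deadline=None)
    def test_loop_terminates_within_three_transforms(self, values):
        res = gamma_correct(np.asarray(values).reshape(1, -1))
        assert res.n_transforms <= 3
        if res.n_transforms < 3:
            assert 0.45 <= res.final_median <= 0.75

    def test_single_transform_moves_median_monotonically(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(0.25, 0.05, (64, 64)), 0.01, 0.99)
        m0 = np.median(img)
        res = gamma_correct(img)
        first = img ** res.gammas_applied[0]
        assert np.median(first) > m0           # brightening for dark images


class TestBoundingBox:
    def test_covers_phantom_foreground(self, expansion_phantom):
        image, labels = expansion_phantom
        box = detect_bounding_box(image)
        ys, xs = np.nonzero(labels != 0)
        inside = ((xs >= box.x1) & (xs < box.x2) & (ys >= box.y1) & (ys < box.y2))
        assert inside.mean() >= 0.99

    def test_constant_image_falls_back_to_full_box(self):
        with pytest.warns(UserWarning, match="variance"):
            box = detect_bounding_box(np.full((40, 60), 7.0))
        assert (box.x1, box.y1, box.x2, box.y2) == (0, 0, 60, 40)

    def test_translation_equivariance(self):
        spec = PhantomSpec(image_size=192, embryo_radius=40, zp_thickness=6,
                           te_thickness=10, icm_radius=13, seed=9)
        image, _ = generate_phantom(spec)
        t = 12
        shifted = np.roll(np.roll(image, t, axis=0), t, axis=1)
        b0 = detect_bounding_box(image)
        b1 = detect_bounding_box(shifted)
        assert abs(b1.x1 - b0.x1 - t) <= 2 and abs(b1.y1 - b0.y1 - t) <= 2

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(5, 5, 5, 10)


class TestCrop:
    def test_full_box_is_identity(self, expansion_phantom):
        image, _ = expansion_phantom
        out = crop(image, BoundingBox(0, 0, 128, 128))
        assert np.array_equal(out, image)

    def test_half_open_arithmetic(self):
        img = np.arange(600).reshape(20, 30)
        out = crop(img, BoundingBox(0, 0, 10, 20))
        assert out.shape == (20, 10)
        assert out[0, 0] == img[0, 0]

    def test_box_outside_image_names_coordinate(self):
        with pytest.raises(ValueError, match="x2"):
            crop(np.zeros((10, 10)), BoundingBox(0, 0, 11, 5))


class TestMinMax:
    def test_two_point_case(self):
        out = minmax_normalize(np.array([[0.2, 0.7]]))
        assert out.ravel() == pytest.approx([0.0, 255.0])

    def test_idempotent_on_full_range(self):
        img = np.linspace(0, 255, 100).reshape(10, 10)
        assert np.allclose(minmax_normalize(img), img)

    def test_constant_image_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_normalize(np.full((5, 5), 3.0))
        assert (out == 0).all()


class TestRescale:
    def test_unit_pixel_size_is_identity(self):
        img = np.random.default_rng(0).random((50, 50))
        assert np.array_equal(rescale_to_physical(img, 1.0), img)

    def test_half_micron_halves_dimensions(self):
        out = rescale_to_physical(np.zeros((200, 200)), 0.5)
        assert out.shape == (100, 100)

    def test_round_trip_error_small_on_smooth_images(self):
        from scipy import ndimage as ndi
        rng = np.random.default_rng(1)
        img = ndi.gaussian_filter(rng.random((128, 128)) * 255, 4)
        down = rescale_to_physical(img, 0.5)
        up = rescale_to_physical(down, 2.0)
        assert np.abs(up - img).mean() < 5.0

    def test_too_small_output_rejected(self):
        with pytest.raises(ValueError):
            rescale_to_physical(np.zeros((100, 100)), 0.1)


class TestPipeline:
    def test_output_range_and_provenance(self, expansion_phantom):
        image, _ = expansion_phantom
        out, prov = preprocess_pipeline(Micrograph(intensities=image))
        assert out.min() == 0.0 and out.max() == 255.0
        assert prov["n_gamma_transforms"] <= 3
        assert len(prov["box"]) == 4

    def test_scale_invariance_across_magnifications(self):
        """The same scene rendered at 0.5 and 1.0 um/px must come out at
        (nearly) the same physical size."""
        spec1 = PhantomSpec(image_size=128, embryo_radius=40, zp_thickness=6,
                            te_thickness=10, icm_radius=13, seed=21,
                            pixel_size_um=1.0)
        spec2 = PhantomSpec(image_size=256, embryo_radius=80, zp_thickness=12,
                            te_thickness=20, icm_radius=26, seed=21,
                            pixel_size_um=0.5)
        img1, _ = generate_phantom(spec1)
        img2, _ = generate_phantom(spec2)
        out1, _ = preprocess_pipeline(Micrograph(img1, pixel_size_um=1.0))
        out2, _ = preprocess_pipeline(Micrograph(img2, pixel_size_um=0.5))
        assert abs(out1.shape[0] - out2.shape[0]) <= 4
        assert abs(out1.shape[1] - out2.shape[1]) <= 4

    def test_brightness_standardization(self, expansion_phantom):
        """A strongly darkened copy must land near the original's median
        after the gamma loop."""
        image, _ = expansion_phantom
        dark = np.clip(np.round(image.astype(float) * 0.3), 0, 255).astype(np.uint8)
        _, prov1 = preprocess_pipeline(Micrograph(image))
        _, prov2 = preprocess_pipeline(Micrograph(dark))
        assert abs(prov1["final_median"] - prov2["final_median"]) < 0.1
        assert prov2["n_gamma_transforms"] >= 1

    def test_mask_follows_geometry(self, expansion_phantom):
        image, labels = expansion_phantom
        out, prov = preprocess_pipeline(Micrograph(image))
        mask_t = preprocess_mask(labels, BoundingBox(*prov["box"]), 1.0)
        assert mask_t.shape == out.shape
        assert set(np.unique(mask_t)) <= {0, 1, 2, 3, 4}
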