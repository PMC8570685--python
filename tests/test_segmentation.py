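import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from swimscore import (
    SegmentationConfig,
    binarize_frame,
    estimate_background,
    measure_mask,
)


def _frame_with_ellipse(shape=(120, 160), center=(60, 80), axes=(12, 20),
                        bg=200, fg=40):
    frame = np.full(shape, bg, dtype=np.uint8)
    rr, cc = draw_ellipse(*center, *axes, shape=shape)
    frame[rr, cc] = fg
    return frame, len(rr)


class TestEstimateBackground:
    POLY = [(50, 30), (110, 30), (110, 90), (50, 90)]  # (x, y)

    def test_uniform_background_fills_uniformly(self):
        frame = np.full((120, 160), 120, dtype=np.uint8)
        rr, cc = draw_disk((60, 80), 15)
        frame[rr, cc] = 30  # dark blob inside the polygon
        model = estimate_background(frame, self.POLY)
        inside = polygon2mask(frame.shape, [(y, x) for x, y in self.POLY])
        assert (model.image[inside] == 120).all()
        np.testing.assert_array_equal(model.image[~inside], frame[~inside])

    def test_no_animal_is_identity_on_uniform_frame(self):
        frame = np.full((120, 160), 77, dtype=np.uint8)
        model = estimate_background(frame, self.POLY)
        np.testing.assert_array_equal(model.image, frame)

    def test_gradient_fill_matches_independent_ring_median(self):
        # horizontal linear gradient with a dark blob; the oracle recomputes
        # the 3-px ring median with scipy.ndimage instead of skimage
        frame = np.tile(np.linspace(50, 200, 160), (120, 1))
        rr, cc = draw_disk((60, 80), 15)
        frame[rr, cc] = 10
        model = estimate_background(frame, self.POLY)
        inside = polygon2mask(frame.shape, [(y, x) for x, y in self.POLY])
        ring = ndimage.binary_dilation(
            inside, structure=ndimage.generate_binary_structure(2, 2),
            iterations=3,
        ) & ~inside
        expected = np.median(frame[ring])
        assert model.image[inside] == pytest.approx(expected)
        assert frame[ring].min() <= expected <= frame[ring].max()

    def test_polygon_covering_frame_raises(self):
        frame = np.full((40, 40), 100, dtype=np.uint8)
        poly = [(-5, -5), (45, -5), (45, 45), (-5, 45)]
        with pytest.raises(ValueError):
            estimate_background(frame, poly)


class TestBinarizeFrame:
    def test_noise_free_ellipse_area_is_exact(self):
        frame, n_px = _frame_with_ellipse()
        cfg = SegmentationConfig(blur_sigma=0.0, min_component_px=1)
        mask = binarize_frame(frame, cfg)
        assert mask.area_px == n_px
        assert not mask.empty

    def test_blank_frame_gives_flagged_empty_mask(self):
        cfg = SegmentationConfig()
        mask = binarize_frame(np.full((60, 60), 128, dtype=np.uint8), cfg)
        assert mask.empty
        assert mask.area_px == 0

    def test_small_components_are_discarded(self):
        frame = np.full((100, 100), 200, dtype=np.uint8)
        rr, cc = draw_disk((30, 30), 13)  # ~530 px blob
        frame[rr, cc] = 40
        rr, cc = draw_disk((80, 80), 3.5)  # ~40 px speck
        frame[rr, cc] = 40
        cfg = SegmentationConfig(blur_sigma=0.0, min_component_px=50)
        mask = binarize_frame(frame, cfg)
        assert not mask.pixels[80, 80]
        assert mask.pixels[30, 30]
        assert 400 < mask.area_px < 600

    def test_deterministic(self):
        frame, _ = _frame_with_ellipse()
        cfg = SegmentationConfig()
        m1 = binarize_frame(frame, cfg)
        m2 = binarize_frame(frame, cfg)
        np.testing.assert_array_equal(m1.pixels, m2.pixels)

    def test_pure_translation_conserves_area(self):
        cfg = SegmentationConfig(blur_sigma=1.0)
        areas = [
            binarize_frame(
                _frame_with_ellipse(center=(60 + dy, 80 + dx))[0], cfg
            ).area_px
            for dy, dx in [(0, 0), (3, -2), (-5, 7), (10, 10)]
        ]
        assert max(areas) <= min(areas) * 1.02  # within +-2%

    def test_background_subtraction_is_polarity_free(self):
        from swimscore.segmentation import BackgroundModel

        dark, _ = _frame_with_ellipse(bg=200, fg=40)
        light, _ = _frame_with_ellipse(bg=40, fg=200)
        cfg = SegmentationConfig(blur_sigma=0.0, use_background=True,
                                 min_component_px=1)
        for frame, bg_level in ((dark, 200), (light, 40)):
            bg = BackgroundModel(
                image=np.full(frame.shape, bg_level, dtype=np.uint8),
                fill_polygon=((0, 0), (1, 0), (1, 1)),
            )
            mask = binarize_frame(frame, cfg, background=bg)
            np.testing.assert_array_equal(
                mask.pixels, dark == 40  # the ellipse pixels
            )

    def test_manual_threshold_polarity(self):
        frame, n_px = _frame_with_ellipse(bg=40, fg=200)
        cfg = SegmentationConfig(
            blur_sigma=0.0, threshold_mode="manual", manual_threshold=120,
            polarity="animal-light", min_component_px=1,
        )
        assert binarize_frame(frame, cfg).area_px == n_px

    def test_otsu_lies_between_two_levels(self):
        frame, _ = _frame_with_ellipse(bg=200, fg=40)
        thr = threshold_otsu(frame.astype(float))
        assert 40 < thr < 200


class TestMeasureMask:
    def test_filled_square_area(self):
        from swimscore.segmentation import BinaryMask

        pixels = np.zeros((30, 30), dtype=bool)
        pixels[10:20, 10:20] = True
        area, _ = measure_mask(BinaryMask(pixels=pixels, area_px=100))
        assert area == 100

    def test_empty_mask_measures_zero(self):
        from swimscore.segmentation import BinaryMask

        mask = BinaryMask(pixels=np.zeros((10, 10), dtype=bool), area_px=0)
        assert measure_mask(mask) == (0, 0.0)

    def test_ellipse_major_axis_within_5pct(self):
        frame, _ = _frame_with_ellipse(axes=(10, 20))  # semi-axes (r, c)
        cfg = SegmentationConfig(blur_sigma=0.0, min_component_px=1)
        _, major = measure_mask(binarize_frame(frame, cfg))
        assert major == pytest.approx(40.0, rel=0.05)
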